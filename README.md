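# sectat

**Screen protein sequences for dual Sec/Tat-targeted polytopic membrane
proteins.**

Most multi-spanning membrane proteins are threaded into the bacterial inner
membrane co-translationally by the Sec translocon. A small but widespread
class — actinobacterial Rieske iron–sulfur proteins, polytopic
heme/molybdenum-cofactor proteins, membrane-anchored polyferredoxins,
YkuE-like metallophosphoesterases — needs *two* machines: Sec inserts the
N-terminal transmembrane domains (TMDs), then the polypeptide is released
and the final TMD, together with a folded cofactor-containing domain, is
handled post-translationally by the twin-arginine translocation (Tat)
pathway. `sectat` finds candidates for this class in protein FASTA input and
quantifies the sequence features that make the hand-over work.

## The screen

For each protein the tool combines three signals:

1. **Twin-arginine (RR) motif** — a consecutive arginine pair, consensus
   context S/T-R-R-x-F-L-K (detection keys on the RR pair; the consensus is
   an optional stringency filter).
2. **TM helix count and position** relative to the motif, from a ΔG-based
   window scan (below) or an imported prediction (TMHMM short format or
   per-residue i/o/M strings).
3. **Orientation** — the probability that the N terminus is cytoplasmic
   (N-in). With an imported prediction its probability is used; otherwise a
   positive-inside-rule score is computed from the K+R bias between
   even- and odd-parity loops, `(P_even + 1) / (P_even + P_odd + 2)`.

A protein is called a candidate when exactly **one** TMD follows the motif
and either

* an **even** number (≥ 2) of TMDs precedes it with N-in score > 0.9
  (class `N-in-even`), or
* an **odd** number (1, 3, 5, 7) precedes it with N-in score < 0.5
  (class `N-out-odd`).

Helix hydrophobicity is scored as the apparent free energy of
translocon-mediated membrane insertion,

```
ΔG_app(s..e) = Σ_i f_aa(res_i, p_i)  [+ ΔG_len(L)]
```

with position-dependent residue contributions `f_aa` from the biological
hydrophobicity scale (Hessa et al. 2005, 2007), transcribed as a versioned
YAML data file. Negative ΔG_app favours Sec insertion. The Tat-dependent
final TMD of every known family scores *positive*, so the screen re-queries
the scanner for the best sub-threshold window downstream of the motif
(`rescue_weak_final_tmd`, on by default).

For classified candidates the **Sec-release feature rubric** reports: final
vs first TMD ΔG_app, K+R count in the 20 residues after the final TMD
(`sec_avoidance` flag at ≥ 2), and the cytoplasmic loop length between the
upstream TMD and the motif (`short_loop` flag below 8 residues, the
approximate minimum for Tat recognition).

## Worked example

Generate one synthetic fixture per architecture and screen them:

```sh
sectat simulate --seed 13 --n-per-arch 1 --out-prefix fx
sectat all fx.fasta -o results.tsv
```

`results.tsv` (columns abridged):

```
id                   class      n_before  n_after  rr_pos  gap  n_in_score  final_tmd_dg  flags           reason
rieske-130091        N-in-even  2         1        119     6    0.923       0.518         weak_final_tmd
moco-131100          N-in-even  4         1        168     5    0.941       0.726         weak_final_tmd
pfd-132109           N-in-even  4         1        193     10   0.941       0.360         weak_final_tmd
ykue-133118          N-out-odd  3         1        137     8    0.077       0.795         weak_final_tmd
neg-norr-134127      none       0         0                     0.900                                     no-RR
neg-twoafter-135136  none       2         2        96           0.941                                     tmd-count
```

Reading the first row: two Sec-dependent TMDs precede the twin arginine at
position 119, one weakly hydrophobic TMD (ΔG_app = +0.52 kcal/mol, hence
`weak_final_tmd`) starts 6 residues after it, and the N terminus is
cytoplasmic (score 0.92 > 0.9) — the Rieske-like dual-targeting
architecture. The control without an RR pair is rejected with reason
`no-RR`; the one with two TMDs downstream of its motif with `tmd-count`.

Other subcommands: `dg` (ΔG_app of an explicit span, with `--variants
S179L,G180L` what-ifs), `topo`, `rr`, `screen`, `features`. All thresholds
can be set in a flat YAML config (`--config`) and are echoed into output
headers for provenance.

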