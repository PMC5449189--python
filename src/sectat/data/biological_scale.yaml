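# Default hydrophobicity scale: the "biological" scale of translocon-mediated
# membrane insertion (Hessa et al. 2005, 2007), transcribed as configuration
# data.  Each residue's contribution to the apparent insertion free energy
# varies with its fractional position along the helix:
#
#   dG(aa, p) = a0 * exp(-a1 * p^2)                          (2 parameters)
#   dG(aa, p) = a0 * exp(-a1 * p^2)
#             + a2 * (exp(-a3*(p-a4)^2) + exp(-a3*(p+a4)^2)) (5 parameters,
#                                                             aromatics W/Y)
#
# where p is the scaled position across the helix, running from -9 at the
# first residue to +9 at the last.  a0 is the contribution at the helix
# centre (p = 0); the symmetric flanking Gaussians for W and Y capture their
# preference for the membrane interface.  Units: kcal/mol.
#
# The helix-length penalty is a smooth bowl, zero at the reference length:
#   dG_len(L) = quadratic * (L - reference_length)^2
# It is applied only when length correction is requested.
name: biological-insertion-scale
version: "1.0"
units: kcal/mol
position_span: 9.0
l_min: 19
l_max: 23
# contribution assigned to the ambiguity residue X (flagged in output)
x_dg: 0.0
length_correction:
  reference_length: 21
  quadratic: 0.0123
profiles:
  A: [0.1267255, 0.0215152]
  C: [-0.0765051, 0.0994228]
  D: [1.7939795, 0.0172643]
  E: [1.4193720, 0.0089351]
  F: [-0.2766953, 0.0010297]
  G: [0.4813492, 0.0047210]
  H: [1.1998590, 0.0080127]
  I: [-0.4597384, 0.0181495]
  K: [1.8485768, 0.0218446]
  L: [-0.4077991, 0.0403902]
  M: [-0.2059488, 0.0193056]
  N: [1.3266132, 0.0092375]
  P: [1.0860888, 0.0100568]
  Q: [1.3336109, 0.0111996]
  R: [1.6492534, 0.0512044]
  S: [0.7023921, 0.0077661]
  T: [0.5266550, 0.0311973]
  V: [-0.3100649, 0.0979201]
  W: [0.2909390, 0.0189282, -0.5479140, 0.0930222, 6.4736619]
  Y: [0.6275249, 0.0103896, -0.5744404, 0.0947821, 6.9164963]
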