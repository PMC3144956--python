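# Nearest-neighbor free-energy parameters (kcal/mol, 37 degC) for the
# hairpin-restricted MFE folder.
#
# Watson-Crick/Watson-Crick stack values follow Xia et al. (1998)
# Biochemistry 37:14719. Stacks involving G.U wobble pairs and the
# size-based loop initiation terms are approximate, Turner-2004-style
# values (Mathews et al. 1999 J Mol Biol 288:911; Turner & Mathews 2010
# NNDB). The model deliberately omits terminal AU/GU penalties, dangling
# ends, coaxial stacking, sequence-dependent loop bonuses and multibranch
# loops; see docs/methods.md. Swapping in another parameter set (e.g. a
# ViennaRNA-derived one) only requires replacing this file.
#
# stacking keys: "XY/ZW" is the motif
#     5'-X Y-3'
#     3'-Z W-5'
# where X.Z is the outer pair and Y.W the inner pair. Symmetric motifs
# (rotate the duplex 180 deg) are stored once; the loader fills in the
# equivalent orientation.
stacking:
  AA/UU: -0.93
  AU/UA: -1.10
  UA/AU: -1.33
  CU/GA: -2.08
  CA/GU: -2.11
  GU/CA: -2.24
  GA/CU: -2.35
  CG/GC: -2.36
  GG/CC: -3.26
  GC/CG: -3.42
  # wobble-containing stacks (approximate)
  AG/UU: -0.55
  AU/UG: -1.36
  UG/AU: -1.27
  UU/AG: -1.00
  CG/GU: -1.41
  CU/GG: -2.11
  GG/CU: -2.51
  GU/CG: -1.53
  GG/UU: -0.50
  GU/UG: 0.47
  UG/GU: 0.30

# loop initiation terms by number of unpaired nucleotides
hairpin_loop:
  3: 5.4
  4: 5.6
  5: 5.7
  6: 5.4
  7: 6.0
  8: 5.5
  9: 6.4

bulge_loop:
  1: 3.8
  2: 2.8
  3: 3.2
  4: 3.6
  5: 4.0
  6: 4.4

internal_loop:
  2: 1.7
  3: 1.8
  4: 2.0
  5: 2.2
  6: 2.5

# Jacobson-Stockmayer extrapolation beyond the tabulated sizes:
#   dG(n) = dG(n_max) + coeff * ln(n / n_max), coeff = 1.75 * R * T
loop_extrapolation_coeff: 1.0785

# penalty per nucleotide of side-length asymmetry in internal loops, capped
internal_asymmetry_per_nt: 0.6
internal_asymmetry_max: 3.0
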