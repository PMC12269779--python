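# Synthetic position/type mismatch weight tables (version synthetic_v1).
#
# These are NOT the published PrimerMiner Position_v1/Type_v1 tables;
# they are a synthetic stand-in constructed to have the same structure
# and qualitative behaviour: the position factor decreases monotonically
# with distance from the 3' terminus (distance 1 = terminal base), the
# type factor is zero on matching concrete pairs, transitions are
# weighted below transversions (with the comparatively stable G:T
# pairing weighted lowest among transversions), and dedicated template
# columns handle gap ('-') and N characters when those are scored
# rather than treated as missing. Drop in a transcription of the
# published tables to reproduce published score magnitudes.
#
# position_factor: multiplier per distance-from-3'-terminus (index 1 =
# terminal base); primers longer than the vector reuse the last value.
# type_factor: rows = primer base, columns = template base.
version: synthetic_v1
position_factor: [120, 90, 60, 45, 30, 24, 20, 16, 13, 10,
                  8, 7, 6, 5, 4, 4, 3, 3, 2, 2, 2, 2, 1, 1, 1]
type_factor:
  A: {A: 0.0, C: 1.4, G: 1.0, T: 1.3, "-": 2.0, N: 1.0}
  C: {A: 1.4, C: 0.0, G: 1.5, T: 1.0, "-": 2.0, N: 1.0}
  G: {A: 1.0, C: 1.5, G: 0.0, T: 1.2, "-": 2.0, N: 1.0}
  T: {A: 1.3, C: 1.0, G: 1.2, T: 0.0, "-": 2.0, N: 1.0}
adjacency_factor: 1.0
gap_as_missing: false
n_as_missing: false
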