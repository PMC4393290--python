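# Synthetic stand-in dinucleotide twist-fluctuation parameter set (degrees).
#
# The dinucleotide-step model of DNA torsional flexibility (Sarai, Mazur,
# Nussinov & Jernigan, Biochemistry 1989) assigns each of the 16 base-pair
# steps the magnitude of its thermal twist-angle fluctuation.  The values
# below are NOT a transcription of that publication: they are a synthetic
# parameter set constructed for this package, calibrated so that
#   * the reverse-complement symmetry value(XY) == value(revcomp(XY)) holds,
#   * the min/max bracket the 7-16 degree range typical of 100 bp window
#     averages reported for this model family,
#   * the TA step is the most torsionally flexible and pyrimidine-purine
#     steps exceed purine-purine steps, reproducing the model's qualitative
#     ordering (AT-rich, TA-periodic tracts are the most flexible sequences).
# Replace this file with transcribed literature values (10 unique steps are
# sufficient; the symmetric partners are filled in at load time) for
# quantitative work on real genomes.
#
# step	twist_fluctuation_deg
AA	7.2
AC	9.4
AG	8.4
AT	13.7
CA	11.4
CC	7.0
CG	10.2
GA	9.0
GC	11.1
TA	16.0
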