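"""Poly(A) cleavage sites cluster around in-peak tandem repeats.

Runs the full pipeline on a simulated study, then measures the distance
from every intense poly(A) cleavage site (score >= 945) to the midpoint of
the nearest (TA)n repeat inside a peak.  The generator places 75% of the
site offsets within 5-25 nt of the repeat midpoint, so the printed
fraction within 25 nt should be close to that; sites further than 500 nt
are discarded as unrelated.
"""

from dnaflex import SynthSpec, polya_distance, run_pipeline, simulate_genome

genomes, manifest = simulate_genome(SynthSpec(seed=4))
result = run_pipeline(genomes, manifest.features, utrs=manifest.utr_records,
                      sites=[s.site for s in manifest.sites])

res = polya_distance([s.site for s in manifest.sites], result.annotations,
                     score_min=945, max_dist=500, families=["(TA)n"])
print(f"intense sites within 500 nt of an in-peak (TA)n repeat: {res.n_retained}")
print(f"  fraction within 25 nt:  {res.frac_within_25:.1%}")
print(f"  fraction within 100 nt: {res.frac_within_100:.1%}")
print("\ndistance histogram (25 nt bins):")
for lo, hi, c in zip(res.bin_edges[:-1], res.bin_edges[1:], res.counts):
    print(f"  [{lo:3d},{hi:3d}) {'#' * int(c)} {c}")
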