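"""Goodness-of-fit tests for Mendelian segregation of a recessive trait.

A curly-leaf mutant crossed to two normal-leaf lines: F1 uniformly normal,
backcrosses to the mutant segregating ~1:1, F2 segregating ~3:1 — the
signature of a single fully penetrant recessive locus.
"""

from bsamap import SegregationObservation, chi_square_gof, classify_inheritance

tables = [
    SegregationObservation([830, 261], [3, 1], label="F2, mutant x USA(0)-26"),
    SegregationObservation([906, 325], [3, 1], label="F2, Yuzhi11 x mutant"),
    SegregationObservation([221, 213], [1, 1], label="BC1, mutant x USA(0)-26"),
    SegregationObservation([174, 165], [1, 1], label="BC1, Yuzhi11 x mutant"),
]
print(f"{'observation':30s} {'ratio':>6s} {'chi2':>6s} {'P':>7s}  fits")
for obs in tables:
    res = chi_square_gof(obs)
    ratio = ":".join(f"{r:g}" for r in obs.expected_ratio)
    print(
        f"{obs.label:30s} {ratio:>6s} {res.chi_square:6.2f} {res.p_value:7.3f}  "
        f"{'yes' if res.fits else 'NO'}"
    )

verdict = classify_inheritance([(32, 0), (26, 0)], tables[2], tables[0])
print(f"\nverdict: {verdict.verdict}")
print(
    "Every chi2 is below the 3.84 cutoff (P > 0.05), and no F1 plant shows"
    " the trait: the counts fit one recessive gene."
)
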