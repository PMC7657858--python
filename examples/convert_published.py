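"""Convert published skew values onto the comparable M scale.

Many comparative datasets report Nonacs' B or Morisita's I_sigma. Given
the sample size N and total offspring R behind each value, these convert
exactly to the multinomial index, putting heterogeneous literatures on
one scale.
"""

from multiskew import convert_to_m

published = [
    # (index reported, value, N, R) — e.g. rows of a comparative table
    ("B", 0.5625, 4, 4),
    ("B", 0.02, 12, 35),
    ("Morisita", 1.8, 10, 42),
    ("WaplesDelta", 0.15, 25, 80),
]

print(f"{'index':>12} {'value':>8} {'N':>4} {'R':>4} {'M-check':>9} {'M':>8}")
for name, value, n, r in published:
    mcheck, m = convert_to_m(name, value, n, r)
    print(f"{name:>12} {value:>8.4f} {n:>4} {r:>4} {mcheck:>9.4f} {m:>8.4f}")

print()
print("M > 0 marks more skew than chance; values from different indices,")
print("group sizes and offspring totals are now directly comparable.")
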