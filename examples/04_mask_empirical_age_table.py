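"""Impose a poorly dated deposit on an empirical-style fossil age table.

The operation used to validate deposit-age estimation on real data:
fossils whose observed age range falls fully inside a chosen interval are
eligible, and a random half (or all) of them get the whole interval as
their age range, emulating the loss of precise dates.
"""

from fbdage.depositsim import impose_deposit_interval

# a synthetic age table in Ma (taxon, observed min, observed max)
age_table = [
    ("taxon_a", 31.0, 33.5), ("taxon_b", 34.2, 36.0), ("taxon_c", 36.5, 40.1),
    ("taxon_d", 40.3, 42.8), ("taxon_e", 42.9, 45.6), ("taxon_f", 30.9, 34.4),
    ("taxon_g", 44.0, 46.5), ("taxon_h", 28.0, 35.0),  # straddles the interval
    ("taxon_i", 50.2, 55.0),                            # older than the interval
]

interval = (30.3, 46.8)
masked = impose_deposit_interval(age_table, interval, fraction=0.5, seed=42)

print(f"deposit interval: {interval[0]}-{interval[1]} Ma, fraction 0.5")
for (taxon, lo, hi), (_, mlo, mhi) in zip(age_table, masked):
    tag = "masked" if (mlo, mhi) == interval else "kept"
    print(f"  {taxon}: observed [{lo:5.1f}, {hi:5.1f}] -> "
          f"[{mlo:5.1f}, {mhi:5.1f}]  ({tag})")
# Only taxa fully inside the interval are eligible (h and i are not);
# exactly half of the eligible taxa, chosen reproducibly by the seed, get
# the wide deposit range. Downstream inference then treats those ranges as
# uniform priors on the fossil ages.
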