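"""Independent brute-force reference implementations used only by tests.

Deliberately naive (dict-and-loop) so they share no code path with the
package's vectorized implementations.
"""

from __future__ import annotations

import math


def brute_total_foliar_cover(pins_df, nonplant_codes) -> float:
    pins: dict = {}
    for row in pins_df.itertuples(index=False):
        pins.setdefault((row.transect_id, row.position_cm), []).append(row.code)
    hits = 0
    for codes in pins.values():
        if any(c not in nonplant_codes for c in codes):
            hits += 1
    return 100.0 * hits / len(pins)


def brute_species_count(pins_df, nonplant_codes) -> int:
    seen = set()
    for row in pins_df.itertuples(index=False):
        if row.code not in nonplant_codes:
            seen.add(row.code)
    return len(seen)


def brute_gap_class_cover(gaps_df, lengths, class_bounds) -> list:
    total = sum(lengths.values())
    sums = [0] * len(class_bounds)
    for row in gaps_df.itertuples(index=False):
        length = row.end_cm - row.start_cm
        for i, (lo, hi) in enumerate(class_bounds):
            if lo <= length <= hi:
                sums[i] += length
                break
    return [100.0 * s / total for s in sums]


def brute_mean_height(heights_df) -> float | None:
    vals = [row.height_cm for row in heights_df.itertuples(index=False)
            if row.height_cm == row.height_cm]  # NaN != NaN
    if not vals:
        return None
    return sum(vals) / len(vals)


def anova_oracle(groups: dict) -> dict:
    """One-way random-effects ANOVA by hand for small examples."""
    means = {g: sum(v) / len(v) for g, v in groups.items()}
    k = len(groups)
    n = sum(len(v) for v in groups.values())
    bias = sum(means.values()) / k
    sse = sum((x - means[g]) ** 2 for g, v in groups.items() for x in v)
    sigma_e2 = sse / (n - k) if n > k else 0.0
    var_means = sum((m - bias) ** 2 for m in means.values()) / (k - 1)
    c = sum(1.0 / len(v) for v in groups.values()) / k
    sigma_b2 = max(0.0, var_means - c * sigma_e2)
    return {"bias": bias, "sigma_e2": sigma_e2, "sigma_b2": sigma_b2,
            "var_means": var_means, "k": k, "n": n}
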