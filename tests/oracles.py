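"""Independent brute-force oracles used to validate the implementation.

These deliberately avoid the code paths they check: the exact-test oracle
works in exact integer arithmetic over explicitly enumerated margin-fixed
tables; the tagging oracle tests every match string at every text position;
the BH oracle evaluates the step-up definition in O(m^2).
"""

from __future__ import annotations

from math import comb

TIE_RTOL = 1e-7  # same tie rule as the implementation, exact arithmetic otherwise


def fisher_oracle(a: int, b: int, c: int, d: int, sidedness: str = "two_sided") -> float:
    """Fisher p by full enumeration of tables with the observed margins.

    Point masses are integer numerators C(r1, x) * C(r2, c1 - x) over the
    common denominator C(N, c1); the two-sided p sums masses <= observed
    (with the published relative tie tolerance applied to exact integers).
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if c1 == 0 or (b + d) == 0:
        return 1.0
    lo, hi = max(0, c1 - r2), min(r1, c1)
    numerators = {x: comb(r1, x) * comb(r2, c1 - x) for x in range(lo, hi + 1)}
    denom = comb(n, c1)
    num_obs = numerators[a]
    if sidedness == "greater":
        total = sum(v for x, v in numerators.items() if x >= a)
    elif sidedness == "less":
        total = sum(v for x, v in numerators.items() if x <= a)
    else:
        total = sum(v for v in numerators.values() if v <= num_obs * (1 + TIE_RTOL))
    return min(total / denom, 1.0)


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n), by direct summation."""
    denom = comb(N, n)
    return sum(comb(K, x) * comb(N - K, n - x)
               for x in range(k, min(K, n) + 1)) / denom


def bh_oracle(p_values) -> list[float]:
    """Benjamini–Hochberg by the O(m^2) definition: for each p_i, the minimum
    over all p_j >= p_i of p_j * m / rank(p_j), capped at 1."""
    m = len(p_values)
    ranked = sorted(range(m), key=lambda i: p_values[i])
    rank_of = {i: r + 1 for r, i in enumerate(ranked)}
    out = []
    for i in range(m):
        candidates = [
            p_values[j] * m / rank_of[j]
            for j in range(m)
            if p_values[j] > p_values[i]
            or (p_values[j] == p_values[i] and rank_of[j] >= rank_of[i])
        ]
        out.append(min(1.0, min(candidates)))
    return out


def naive_candidates(text: str, lexicon) -> list[tuple[int, int, str, int, str]]:
    """Every boundary-valid occurrence of every match string, by position scan."""
    out = []
    for idx, entry in enumerate(lexicon):
        for s, cs in zip(entry.match_strings, entry.case_sensitive):
            hay = text if cs else text.lower()
            needle = s if cs else s.lower()
            for start in range(len(text) - len(s) + 1):
                if hay[start:start + len(needle)] != needle:
                    continue
                left_ok = start == 0 or not (
                    text[start - 1].isalnum() and text[start - 1].isascii()
                )
                end = start + len(s)
                right_ok = end == len(text) or not (
                    text[end].isalnum() and text[end].isascii()
                )
                if left_ok and right_ok:
                    out.append((start, end, entry.target_id, idx, s))
    return out


def naive_tag_text(text: str, lexicon) -> set[str]:
    """Naive matcher: position scan, then the published resolution rule
    (longest first, then leftmost, then lexicon order) and the blacklist."""
    candidates = naive_candidates(text, lexicon)
    ordered = sorted(candidates, key=lambda c: (-(c[1] - c[0]), c[0], c[3]))
    taken = []
    for cand in ordered:
        # identical spans co-attribute (symbol collisions); partial overlaps lose
        if any(cand[0] == t[0] and cand[1] == t[1] for t in taken):
            taken.append(cand)
        elif all(cand[1] <= t[0] or t[1] <= cand[0] for t in taken):
            taken.append(cand)
    hits = set()
    for _, _, target_id, _, string in taken:
        blocked = any(
            bl_s.lower() == string.lower() and (bl_c in ("", "*") or bl_c in text)
            for bl_s, bl_c in lexicon.blacklist
        )
        if not blocked:
            hits.add(target_id)
    return hits
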