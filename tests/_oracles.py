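"""Independent brute-force oracles used only by the test suite.

Each oracle re-derives an operation's expected output from first principles
(base-pairing walks, exhaustive enumeration, exact rational arithmetic) and
never calls the code path it checks.
"""

from fractions import Fraction
from math import comb

# target DNA base paired with miRNA RNA base, Watson-Crick only
PAIRS = {("A", "U"), ("C", "G"), ("G", "C"), ("T", "A")}

SITE_ORDER = ("8mer", "7mer-m8", "7mer-A1", "6mer")


def brute_force_seed_matches(seq: str, mirna: str):
    """All canonical seed matches by per-window base-pairing, strongest type
    per locus (a weaker match contained in a stronger one is dropped).

    Returns a sorted list of (site_type, start, end), 1-based inclusive.
    """

    def paired(i, pos):  # target index (0-based) vs miRNA position (1-based)
        return (seq[i], mirna[pos - 1]) in PAIRS

    raw = []
    L = len(seq)
    for i in range(L):
        if i + 8 <= L and seq[i + 7] == "A" and \
                all(paired(i + k, 8 - k) for k in range(7)):
            raw.append(("8mer", i + 1, i + 8))
        if i + 7 <= L and all(paired(i + k, 8 - k) for k in range(7)):
            raw.append(("7mer-m8", i + 1, i + 7))
        if i + 7 <= L and seq[i + 6] == "A" and \
                all(paired(i + k, 7 - k) for k in range(6)):
            raw.append(("7mer-A1", i + 1, i + 7))
        if i + 6 <= L and all(paired(i + k, 7 - k) for k in range(6)):
            raw.append(("6mer", i + 1, i + 6))

    rank = {t: r for r, t in enumerate(SITE_ORDER)}
    kept = []
    for t, s, e in raw:
        contained = any(
            rank[t2] < rank[t] and s2 <= s and e <= e2
            for t2, s2, e2 in raw if (t2, s2, e2) != (t, s, e))
        if not contained:
            kept.append((t, s, e))
    kept.sort(key=lambda m: (m[1], rank[m[0]]))
    return kept


def brute_force_region_calls(variant_pos, variant_chrom, models):
    """Region kind per covering transcript by enumerating every
    (transcript, interval) pair; returns (calls, exclusive_flag)."""

    def norm(c):
        c = str(c)
        return c[3:] if c.lower().startswith("chr") else c

    calls = []
    for m in sorted(models, key=lambda m: m.transcript_id):
        if norm(m.chrom) != norm(variant_chrom):
            continue
        hit_kinds = [k for k, s, e in m.regions if s <= variant_pos <= e]
        starts = [s for _, s, _ in m.regions]
        ends = [e for _, _, e in m.regions]
        if min(starts) <= variant_pos <= max(ends):
            calls.append((m.transcript_id,
                          hit_kinds[0] if hit_kinds else "unannotated"))
    exclusive = bool(calls) and all(k == "three_prime_utr" for _, k in calls)
    return calls, exclusive


def exact_fisher_two_sided(a, b, c, d) -> Fraction:
    """Two-sided Fisher p by exhaustive enumeration in exact rationals."""
    row1, row2, col1 = a + b, c + d, a + c
    n = row1 + row2
    if n == 0:
        return Fraction(1)
    denom = comb(n, col1)
    w_obs = comb(row1, a) * comb(row2, col1 - a)
    tail = 0
    for k in range(max(0, col1 - row2), min(col1, row1) + 1):
        w = comb(row1, k) * comb(row2, col1 - k)
        if w <= w_obs:
            tail += w
    return Fraction(tail, denom)


def double_loop_motif_counts(motif: str, sequences):
    """Presence/occurrence counts by a regex-free double loop."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    rc = "".join(comp[b] for b in reversed(motif))
    n_present = 0
    occurrences = 0
    for seq in sequences:
        hits = 0
        for i in range(len(seq) - len(motif) + 1):
            w = seq[i:i + len(motif)]
            if w == motif or w == rc:
                hits += 1
        occurrences += hits
        if hits:
            n_present += 1
    return n_present, occurrences, len(sequences)
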