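"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by a different route than the package
(naive sliding windows on an explicitly doubled sequence, scanning the
reverse-complemented genome instead of per-window complements, exact
rational hypergeometric sums) so agreement is informative.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def rc(s: str) -> str:
    return "".join(_COMP[b] for b in reversed(s))


def naive_match(pattern: str, window: str) -> bool:
    return all(b in IUPAC[p] for p, b in zip(pattern, window))


def brute_scan(seq: str, pattern: str, dedup: bool = True) -> list[tuple[int, str]]:
    """All (duplex_start, strand) recognition sites on a circular duplex.

    Top-strand matches come from sliding the pattern over seq+seq; bottom
    matches from sliding it over the reverse complement of the whole genome
    and mapping coordinates back (a bottom match at revcomp index j covers
    top-strand window starting at L - j - k, modulo L).
    """
    L, k = len(seq), len(pattern)
    doubled = seq + seq
    tops = {i for i in range(L) if naive_match(pattern, doubled[i : i + k])}
    rseq = rc(seq)
    rdoubled = rseq + rseq
    bottoms = set()
    for j in range(L):
        if naive_match(pattern, rdoubled[j : j + k]):
            bottoms.add((L - j - k) % L)
    out = [(i, "top") for i in tops]
    for i in bottoms:
        if not (dedup and i in tops):
            out.append((i, "bottom"))
    return sorted(out, key=lambda t: (t[0], t[1] != "top"))


def fisher_two_sided(a: int, b: int, c: int, d: int) -> Fraction:
    """Exact two-sided Fisher p: sum of hypergeometric probabilities of all
    tables with the same margins whose probability does not exceed the
    observed table's (with a tiny relative tolerance, as is conventional)."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)
    p_obs = Fraction(comb(r1, a) * comb(r2, c1 - a), denom)
    cutoff = p_obs * Fraction(10**9 + 1, 10**9)
    total = Fraction(0)
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        pk = Fraction(comb(r1, k) * comb(r2, c1 - k), denom)
        if pk <= cutoff:
            total += pk
    return min(total, Fraction(1))


def brute_designable_mask(seq: str, pattern: str, nick_offset: int,
                          flank: int, dedup: bool = True) -> list[bool]:
    """Per-position designability by direct circular-distance checks."""
    L = len(seq)
    k = len(pattern)
    nicks = []
    for start, strand in brute_scan(seq, pattern, dedup=dedup):
        if strand == "top":
            nicks.append((start + nick_offset) % L)
        else:
            nicks.append((start + k - 1 - nick_offset) % L)
    mask = []
    for p in range(L):
        ok = False
        for q in nicks:
            d = abs(p - q)
            if min(d, L - d) <= flank:
                ok = True
                break
        mask.append(ok)
    return mask


def brute_enumerate_designs(seq: str, target_1based: int, ref: str, desired: str,
                            motif: str, palindromic: bool,
                            window_min: int = 8, window_max: int = 24,
                            arm_min: int = 14, arm_max: int = 18,
                            require_preceding_t: bool = True,
                            ) -> set[tuple]:
    """Exhaustive loop over (window start, window length, motif anchor,
    nickase side, arm lengths) applying every design constraint directly on
    the doubled sequence. Returns a set of design signatures:
    (window_start, window_len, anchor_start, nickase_side, left_len,
    right_len, nick_strand, edited_strand, gap).
    """
    L = len(seq)
    doubled = seq + seq + seq  # generous for arm overhangs
    t0 = target_1based - 1
    assert seq[t0] == ref
    request_table = {("A", "G"): "top", ("T", "C"): "bottom",
                     ("C", "T"): "top", ("G", "A"): "bottom"}
    need_strand = request_table[(ref, desired)]
    k = len(motif)
    sites = brute_scan(seq, motif, dedup=True)
    out = set()
    for wlen in range(window_min, window_max + 1):
        for ws in range(L):
            # target inside window (circular)
            if (t0 - ws) % L >= wlen:
                continue
            for (astart, astrand) in sites:
                r = (astart - ws) % L
                if r + k > wlen:
                    continue
                for side in ("left", "right"):
                    gap = r if side == "left" else wlen - (r + k)
                    if 0 <= gap <= 4:
                        outcome = "opposite"
                    elif 5 <= gap <= 9:
                        outcome = "same"
                    else:
                        continue
                    tale_strand = "top" if side == "left" else "bottom"
                    nick = (tale_strand if outcome == "same"
                            else ("bottom" if tale_strand == "top" else "top"))
                    if not palindromic and nick != astrand:
                        continue
                    edited = "bottom" if nick == "top" else "top"
                    if edited != need_strand:
                        continue
                    for ll in range(arm_min, arm_max + 1):
                        if require_preceding_t and doubled[(ws - ll - 1) % L + L] != "T":
                            continue
                        for rl in range(arm_min, arm_max + 1):
                            if require_preceding_t and \
                                    _COMP[doubled[(ws + wlen + rl) % L + L]] != "T":
                                continue
                            out.add((ws, wlen, astart, side, ll, rl, nick,
                                     edited, gap))
    return out
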