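"""Independent brute-force oracles used by the test suite.

These re-derive annealing, digestion and motif scanning from first
principles — position-by-position, with no shared code paths with the
package — so that agreement with the package is a real check.
"""

from __future__ import annotations

_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}


def brute_revcomp(s: str) -> str:
    return "".join(_COMP[c] for c in reversed(s))


def brute_stretches(a: str, b: str, min_len: int) -> list[tuple[int, int, int]]:
    """All maximal antiparallel complementary stretches >= min_len.

    Returned as (a_start, b_end_halfopen, length), testing every start pair
    directly: position a_start+k pairs with b_end-1-k.
    """

    def paired(i: int, j: int) -> bool:
        return 0 <= i < len(a) and 0 <= j < len(b) and _COMP[a[i]] == b[j]

    found = []
    for i in range(len(a)):
        for j in range(len(b)):
            # stretch starting at (i, j) must be maximal: no pair just before
            if paired(i - 1, j + 1):
                continue
            length = 0
            while paired(i + length, j - length):
                length += 1
            if length >= min_len:
                found.append((i, j + 1, length))
    return found


def brute_greedy_anneal(a: str, b: str, min_len: int) -> set[tuple[int, int]]:
    """Greedy maximal-stretch annealing, re-derived: decreasing length,
    ties leftmost on strand A then on strand B; conflicting stretches
    skipped whole.  Returns the accepted base pairs."""
    stretches = brute_stretches(a, b, min_len)
    stretches.sort(key=lambda s: (-s[2], s[0], s[1] - s[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: set[tuple[int, int]] = set()
    for a_start, b_end, length in stretches:
        pos_a = set(range(a_start, a_start + length))
        pos_b = set(range(b_end - length, b_end))
        if pos_a & used_a or pos_b & used_b:
            continue
        used_a |= pos_a
        used_b |= pos_b
        for k in range(length):
            pairs.add((a_start + k, b_end - 1 - k))
    return pairs


def brute_digest(strand: str, paired_positions: set[int]) -> list[str]:
    """Apply the T1 cut rule position by position: cut 3' of every unpaired
    G; return the fragment strings 5'->3'."""
    frags = []
    cur = []
    for pos, ch in enumerate(strand):
        cur.append(ch)
        if ch == "G" and pos not in paired_positions:
            frags.append("".join(cur))
            cur = []
    if cur:
        frags.append("".join(cur))
    return frags


def brute_duplex_products(
    a: str, b: str, pairs: set[tuple[int, int]]
) -> list[tuple[str, str]]:
    """Duplex products by direct fragment-interval bookkeeping.

    Returns sorted (fragment_a, fragment_b) residue pairs for every pair of
    fragments sharing at least one base pair 1-to-1 (complex groupings are
    excluded, mirroring the duplex class only).
    """
    paired_a = {i for i, _ in pairs}
    paired_b = {j for _, j in pairs}

    def intervals(strand: str, paired: set[int]) -> list[tuple[int, int]]:
        out, lo = [], 0
        for pos, ch in enumerate(strand):
            if ch == "G" and pos not in paired:
                out.append((lo, pos + 1))
                lo = pos + 1
        if lo < len(strand):
            out.append((lo, len(strand)))
        return out

    iv_a = intervals(a, paired_a)
    iv_b = intervals(b, paired_b)

    def find(ivs, pos):
        for n, (lo, hi) in enumerate(ivs):
            if lo <= pos < hi:
                return n
        raise AssertionError

    links: dict[tuple[int, int], int] = {}
    for i, j in pairs:
        key = (find(iv_a, i), find(iv_b, j))
        links[key] = links.get(key, 0) + 1
    partners_a: dict[int, set[int]] = {}
    partners_b: dict[int, set[int]] = {}
    for fa, fb in links:
        partners_a.setdefault(fa, set()).add(fb)
        partners_b.setdefault(fb, set()).add(fa)
    duplexes = []
    for (fa, fb) in links:
        if len(partners_a[fa]) == 1 and len(partners_b[fb]) == 1:
            lo_a, hi_a = iv_a[fa]
            lo_b, hi_b = iv_b[fb]
            duplexes.append((a[lo_a:hi_a], b[lo_b:hi_b]))
    return sorted(duplexes)


def brute_scan(motif: str, utrs) -> dict[str, int]:
    """Naive sliding-window scan; returns per-ID occurrence counts (>0)."""
    hits = {}
    for u in utrs:
        count = sum(
            1
            for i in range(len(u.residues) - len(motif) + 1)
            if u.residues[i : i + len(motif)] == motif
        )
        if count:
            hits[u.id] = count
    return hits
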