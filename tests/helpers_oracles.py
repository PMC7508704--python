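"""Independent brute-force oracles used to validate the package.

Everything here is deliberately written from first principles — naive
enumeration and hand-rolled walks — and stays independent of the code
paths it checks.
"""

from __future__ import annotations

from itertools import combinations


# ---------------------------------------------------------------------------
# conflict-filter oracle

def _standard(a: str, b: str) -> bool:
    return {a, b} in ({"A", "U"}, {"G", "C"}, {"G", "U"})


def conflict_key(pair: tuple[int, int], score: float,
                 all_pairs: set[tuple[int, int]], sequence: str) -> tuple:
    i, j = pair
    neighbour = (i - 1, j + 1) in all_pairs or (i + 1, j - 1) in all_pairs
    return (j - i > 4, _standard(sequence[i - 1], sequence[j - 1]), neighbour,
            score, -(j - i), -i, -j)


def brute_force_resolve(
    candidates: list[tuple[tuple[int, int], float]], sequence: str
) -> set[tuple[int, int]]:
    """Conflict-free subset whose descending key sequence is lexicographically
    greatest, found by exhaustive enumeration of all subsets."""
    all_pairs = {p for p, _ in candidates}
    keys = [conflict_key(p, s, all_pairs, sequence) for p, s in candidates]
    best_seq, best_set = None, set()
    n = len(candidates)
    for mask in range(1 << n):
        used: set[int] = set()
        ok = True
        chosen = []
        for k in range(n):
            if not mask >> k & 1:
                continue
            i, j = candidates[k][0]
            if i in used or j in used:
                ok = False
                break
            used.update((i, j))
            chosen.append(k)
        if not ok:
            continue
        seq = tuple(sorted((keys[k] for k in chosen), reverse=True))
        if best_seq is None or seq > best_seq:
            best_seq, best_set = seq, {candidates[k][0] for k in chosen}
    return best_set


# ---------------------------------------------------------------------------
# crossing-removal oracle

def _crosses(p: tuple[int, int], q: tuple[int, int]) -> bool:
    (i, j), (k, l) = sorted((p, q))
    return i < k < j < l


def brute_force_max_noncrossing(pairs: list[tuple[int, int]]) -> int:
    """Cardinality of the largest crossing-free subset, by enumeration."""
    best = 0
    for r in range(len(pairs), 0, -1):
        if r <= best:
            break
        for subset in combinations(pairs, r):
            if not any(_crosses(p, q) for p, q in combinations(subset, 2)):
                best = max(best, r)
                break
    return best


# ---------------------------------------------------------------------------
# naive SSE classification oracle

def naive_partner_map(structure: str) -> dict[int, int]:
    stack: list[int] = []
    partner: dict[int, int] = {}
    for pos, ch in enumerate(structure, start=1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            i = stack.pop()
            partner[i] = pos
            partner[pos] = i
    return partner


def naive_stems(structure: str) -> list[list[tuple[int, int]]]:
    partner = naive_partner_map(structure)
    pairs = sorted((i, j) for i, j in partner.items() if i < j)
    stems: list[list[tuple[int, int]]] = []
    for i, j in pairs:
        if stems and stems[-1][-1] == (i - 1, j + 1):
            stems[-1].append((i, j))
        else:
            stems.append([(i, j)])
    return stems


def naive_classify(structure: str) -> list[tuple[tuple[int, int], str, int]]:
    """For each stem, walk its interior loop and classify it.

    Returns (inner pair, loop type, number of incident stems) per stem,
    plus an entry keyed ``(0, len+1)`` for the exterior loop when it holds
    unpaired residues or more than one top-level stem.
    """
    partner = naive_partner_map(structure)
    n = len(structure)
    out: list[tuple[tuple[int, int], str, int]] = []

    def walk(lo: int, hi: int) -> tuple[int, list[int]]:
        """Children stems and unpaired gap sizes strictly inside (lo, hi)."""
        children = 0
        gaps: list[int] = []
        gap = 0
        k = lo + 1
        while k < hi:
            if k in partner and partner[k] > k:
                children += 1
                gaps.append(gap)
                gap = 0
                k = partner[k] + 1
            else:
                gap += 1
                k += 1
        gaps.append(gap)
        return children, gaps

    for stem in naive_stems(structure):
        ii, ij = stem[-1]
        children, gaps = walk(ii, ij)
        if children == 0:
            kind = "hairpin_loop"
        elif children == 1:
            kind = "internal_loop" if all(g > 0 for g in gaps) else "bulge_loop"
        else:
            kind = "junction"
        out.append(((ii, ij), kind, children + 1))

    children, gaps = walk(0, n + 1)
    if children >= 2 or any(g > 0 for g in gaps):
        if children >= 1:
            out.append(((0, n + 1), "open_loop", children))
    return out


def enumerate_nested(length: int):
    """All nested dot-bracket strings of exactly the given length."""
    results: list[str] = []

    def rec(prefix: str, open_count: int, remaining: int):
        if remaining == 0:
            if open_count == 0:
                results.append(prefix)
            return
        rec(prefix + ".", open_count, remaining - 1)
        if remaining > open_count:
            rec(prefix + "(", open_count + 1, remaining - 1)
        if open_count > 0:
            rec(prefix + ")", open_count - 1, remaining - 1)

    rec("", 0, length)
    return results
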