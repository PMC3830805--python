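"""Exhaustive re-implementation of the five-step quartet scan, used only as
an independent cross-check. Shares no code with the package: plain lists,
explicit loops, its own split bookkeeping."""

from itertools import combinations


def oracle_scan(names, rows, og):
    """names: list of row names; rows: dict name -> list of 0/1; og: name.

    Returns a sorted list of call tuples
    (recombinant, parent_forward, parent_backward, interval_left, interval_right).
    """
    ingroup = [n for n in names if n != og]
    universe = ingroup + [og]
    L = len(rows[og])

    # Step A: singleton counts over the whole analysed set + outgroup
    singletons = {n: 0 for n in universe}
    for j in range(L):
        ones = [n for n in universe if rows[n][j] == 1]
        if len(ones) == 1:
            singletons[ones[0]] += 1

    survivors = []
    for trio in combinations(sorted(ingroup), 3):
        # Step B: classify informative sites into the three splits
        splits = {}
        for a, b in combinations(trio, 2):
            splits[(a, b)] = []
        for j in range(L):
            vals = {n: rows[n][j] for n in list(trio) + [og]}
            if sum(vals.values()) != 2:
                continue
            ones = frozenset(n for n in vals if vals[n] == 1)
            for a, b in splits:
                c = [n for n in trio if n not in (a, b)][0]
                if ones == frozenset((a, b)) or ones == frozenset((c, og)):
                    splits[(a, b)].append(j + 1)
        # Step C: exactly one empty split; candidate grouped with outgroup
        empty = [p for p in splits if not splits[p]]
        if len(empty) != 1:
            continue
        cand = [n for n in trio if n not in empty[0]][0]
        filled = [(p, s) for p, s in splits.items() if s]
        (p1, s1), (p2, s2) = filled
        # Step D: disjoint positional ranges
        lo1, hi1 = min(s1), max(s1)
        lo2, hi2 = min(s2), max(s2)
        if not (hi1 < lo2 or hi2 < lo1):
            continue
        if hi1 < lo2:
            fwd_pair, fwd, bwd_pair, bwd = p1, s1, p2, s2
        else:
            fwd_pair, fwd, bwd_pair, bwd = p2, s2, p1, s1
        parent_f = [n for n in fwd_pair if n != cand][0]
        parent_b = [n for n in bwd_pair if n != cand][0]
        parents_sum = sum(singletons[n] for n in trio if n != cand)
        survivors.append(
            (
                singletons[cand],
                -parents_sum,
                (cand, parent_f, parent_b, max(fwd), min(bwd)),
            )
        )
    if not survivors:
        return []
    # Step E: fewest candidate singletons, then largest parental sum; ties kept
    best = min(s[:2] for s in survivors)
    return sorted(call for a, b, call in survivors if (a, b) == best)
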