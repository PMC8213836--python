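"""Independent brute-force replay of the sequential saturation rules.

Used as an oracle against the optimized simulator.  Deliberately naive: a
full pairwise distance matrix, explicit python loops, and the shared binding
order contract — the initial lever of each molecule is
``sorted_eligible[floor(u * len(sorted_eligible))]`` for the next uniform
variate ``u``.  Nothing here imports the implementation under test.
"""

from __future__ import annotations

import math


def brute_force_saturate(anchors, reach, uniforms):
    """Replay the saturation rules literally.

    Parameters
    ----------
    anchors:
        List of (x, y) tuples.
    reach:
        Maximal bridgeable anchor-to-anchor distance.
    uniforms:
        Iterator of U(0,1) variates consumed one per molecule.

    Returns
    -------
    (bridges, molecules):
        ``bridges`` is a set of ordered (i, j) pairs with i < j; ``molecules``
        a list of (lever_a, lever_b_or_None).
    """
    n = len(anchors)
    dist = [
        [
            math.hypot(anchors[i][0] - anchors[j][0], anchors[i][1] - anchors[j][1])
            for j in range(n)
        ]
        for i in range(n)
    ]
    free = [2] * n
    bridges = set()
    molecules = []
    uniforms = iter(uniforms)
    while any(f > 0 for f in free):
        eligible = sorted(i for i in range(n) if free[i] > 0)
        u = next(uniforms)
        a = eligible[int(u * len(eligible))]
        free[a] -= 1
        # closest *other* lever with a free site within reach; ties -> lowest index
        best, best_d = None, None
        for j in range(n):
            if j == a or free[j] <= 0:
                continue
            d = dist[a][j]
            if d <= reach and (best_d is None or d < best_d):
                best, best_d = j, d
        if best is None:
            molecules.append((a, None))
        else:
            free[best] -= 1
            bridges.add((min(a, best), max(a, best)))
            molecules.append((a, best))
    return bridges, molecules


def brute_force_interlinked_fraction(bridges, n_levers):
    touched = set()
    for a, b in bridges:
        touched.add(a)
        touched.add(b)
    return len(touched) / n_levers
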