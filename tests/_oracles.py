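"""Independent brute-force oracles used to check the package's algorithms.

These deliberately re-derive results by exhaustive enumeration rather than
calling the code paths they verify.
"""

from __future__ import annotations

import numpy as np


def brute_force_ssrs(seq: str, min_repeats: dict[int, int]
                     ) -> list[tuple[int, int, str, int]]:
    """Exhaustive SSR scan: every start position x every unit length.

    For each unit length, all qualifying tandem runs are enumerated and then
    reduced to a non-overlapping set by a leftmost-greedy sweep.  Returns
    sorted (start, end, unit, repeat_count) tuples.
    """
    seq = seq.upper()
    out: list[tuple[int, int, str, int]] = []
    for unit_len, min_r in sorted(min_repeats.items()):
        runs = []
        for i in range(len(seq) - unit_len + 1):
            unit = seq[i:i + unit_len]
            if "N" in unit:
                continue
            if any(unit_len % d == 0 and unit == unit[:d] * (unit_len // d)
                   for d in range(1, unit_len)):
                continue  # non-primitive unit
            k = 1
            while seq[i + k * unit_len:i + (k + 1) * unit_len] == unit:
                k += 1
            if k >= min_r:
                runs.append((i, i + k * unit_len, unit, k))
        last_end = -1
        for start, end, unit, k in runs:  # already sorted by start
            if start >= last_end:
                out.append((start, end, unit, k))
                last_end = end
    return sorted(out)


def random_additive_tree(rng: np.random.Generator, n_leaves: int):
    """A random binary tree topology with positive branch lengths, plus its
    exact leaf-to-leaf path-length (additive) distance matrix.

    The tree is built by random sequential joins; distances are accumulated
    directly from the join structure, independent of any tree library.
    Returns (newick string, leaf names, distance matrix ndarray).
    """
    leaves = [f"L{i}" for i in range(n_leaves)]
    index = {name: k for k, name in enumerate(leaves)}
    D = np.zeros((n_leaves, n_leaves))
    # each live node: (newick, {leaf: distance from leaf to this node's root});
    # cross-pair distances are fixed into D at the join that separates them
    nodes = [(name, {name: 0.0}) for name in leaves]

    def fix_cross(d_i, d_j, bi, bj):
        for la, da in d_i.items():
            for lb, db in d_j.items():
                D[index[la], index[lb]] = D[index[lb], index[la]] = \
                    da + bi + db + bj
    while len(nodes) > 2:
        i, j = sorted(int(x) for x in
                      rng.choice(len(nodes), size=2, replace=False))
        (nwk_j, d_j) = nodes.pop(j)
        (nwk_i, d_i) = nodes.pop(i)
        bi = float(rng.uniform(0.1, 1.0))
        bj = float(rng.uniform(0.1, 1.0))
        fix_cross(d_i, d_j, bi, bj)
        merged = {**{l: d + bi for l, d in d_i.items()},
                  **{l: d + bj for l, d in d_j.items()}}
        nodes.append((f"({nwk_i}:{bi},{nwk_j}:{bj})", merged))
    (nwk_a, d_a), (nwk_b, d_b) = nodes
    bridge = float(rng.uniform(0.1, 1.0))
    fix_cross(d_a, d_b, bridge, 0.0)
    return f"({nwk_a}:{bridge / 2},{nwk_b}:{bridge / 2});", leaves, D
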