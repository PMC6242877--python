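"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (exhaustive enumeration, quadratic
DP written from scratch) and shares no code with the package paths it
checks.
"""

from __future__ import annotations

import itertools
import math
import re

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}


def nw_identity(seq_a: str, seq_b: str) -> int:
    """Max identical aligned positions (match 1 / mismatch 0 / indel 0)."""
    n, m = len(seq_a), len(seq_b)
    dp = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            dp[i][j] = max(
                dp[i - 1][j - 1] + (1 if seq_a[i - 1] == seq_b[j - 1] else 0),
                dp[i - 1][j],
                dp[i][j - 1],
            )
    return dp[n][m]


def brute_force_dollo(tree, presence: dict[str, int]):
    """Exhaustive single-gain minimum-loss reconstructions.

    Assigns presence/absence to every internal node, requires exactly one
    0->1 edge (treating a virtual all-absent root parent), and returns the
    set of optimal ``(gain_branch, frozenset(loss_branches))`` together
    with the minimal loss count.
    """
    nodes = list(tree.preorder())
    internal = [n for n in nodes if not n.is_leaf]
    state: dict[str, int] = {}
    best: dict = {"losses": math.inf, "solutions": set()}

    def edges():
        out = []
        for n in nodes:
            if n is tree.root:
                parent_state = 0  # virtual absent ancestor above the root
            else:
                parent_state = state[n.parent.label]
            out.append((n.label, parent_state, state[n.label]))
        return out

    def evaluate():
        gains = [
            lbl for lbl, ps, cs in edges() if ps == 0 and cs == 1
        ]
        losses = [
            lbl for lbl, ps, cs in edges() if ps == 1 and cs == 0
        ]
        if len(gains) != 1:
            return
        gain = gains[0]
        gain_branch = "root" if gain == tree.root.label else gain
        if len(losses) < best["losses"]:
            best["losses"] = len(losses)
            best["solutions"] = {(gain_branch, frozenset(losses))}
        elif len(losses) == best["losses"]:
            best["solutions"].add((gain_branch, frozenset(losses)))

    for leaf in tree.root.leaves():
        state[leaf.label] = presence.get(leaf.label, 0)
    for assignment in itertools.product((0, 1), repeat=len(internal)):
        for node, s in zip(internal, assignment):
            state[node.label] = s
        evaluate()
    return best["solutions"], best["losses"]


def regex_site_scan(utr: str, seed7: str) -> list[tuple[int, str]]:
    """All canonical seed-match sites via independent regex lookahead."""
    m = "".join(_COMP[c] for c in reversed(seed7))
    m7a1 = m[1:]
    out = []
    for match in re.finditer(f"(?={re.escape(m)})", utr):
        off = match.start()
        stype = "8mer" if utr[off + 7 : off + 8] == "A" else "7mer-m8"
        out.append((off, stype))
    for match in re.finditer(f"(?={re.escape(m7a1)}A)", utr):
        off = match.start()
        if off > 0 and utr[off - 1] == m[0]:
            continue
        out.append((off, "7mer-A1"))
    return sorted(out)


def exact_hypergeom_upper(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) by direct combinatorial summation."""
    total = math.comb(N, n)
    acc = 0
    for x in range(k, min(K, n) + 1):
        acc += math.comb(K, x) * math.comb(N - K, n - x)
    return acc / total


def enumerate_nested_structures(seq: str, min_loop: int = 3):
    """All nested structures over WC+GU pairs; yields (n_pairs, dotbracket).

    Exponential; only for very short sequences.
    """
    pairs = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}
    n = len(seq)
    candidates = [
        (i, j)
        for i in range(n)
        for j in range(i + min_loop + 1, n)
        if (seq[i], seq[j]) in pairs
    ]

    def compatible(p, chosen):
        i, j = p
        for a, b in chosen:
            if len({i, j, a, b}) < 4:
                return False
            if (a < i < b < j) or (i < a < j < b):
                return False  # crossing
        return True

    best: list[tuple[int, str]] = []

    def rec(idx, chosen):
        if idx == len(candidates):
            s = ["."] * n
            for a, b in chosen:
                s[a], s[b] = "(", ")"
            best.append((len(chosen), "".join(s)))
            return
        rec(idx + 1, chosen)
        if compatible(candidates[idx], chosen):
            rec(idx + 1, chosen + [candidates[idx]])

    rec(0, [])
    return best
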