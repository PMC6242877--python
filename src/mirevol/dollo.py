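"""Dollo-parsimony gain/loss reconstruction and net gain rates.

Under the Dollo model a binary character (presence of an orthogroup) is
gained exactly once and may subsequently be lost any number of times.  The
minimum-loss reconstruction places the gain on the branch above the most
recent common ancestor (MRCA) of the present leaves and the losses on the
stems of the maximal all-absent subtrees below the gain node: moving the
gain above the MRCA can only add lost subtrees, so this placement is the
unique parsimony optimum.

Branch-specific net gain rates are ``(gains - losses) / branch length`` in
events per million years.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

from .orthogroups import OrthogroupMatrix
from .tree import ROOT_BRANCH, DatedTree, TreeNode

logger = logging.getLogger(__name__)


@dataclass
class GainLossReconstruction:
    """Per-orthogroup gain/loss placements and per-branch totals."""

    gain_branch: dict[str, str] = field(default_factory=dict)  # og -> branch
    loss_branches: dict[str, set[str]] = field(default_factory=dict)
    gains: dict[str, int] = field(default_factory=dict)  # branch -> count
    losses: dict[str, int] = field(default_factory=dict)

    def net_rates(
        self, tree: DatedTree, root_stem_length: float = 1.0
    ) -> dict[str, float]:
        out = {}
        for branch in tree.branch_labels():
            g = self.gains.get(branch, 0)
            l = self.losses.get(branch, 0)
            out[branch] = net_rate(
                g, l, tree.branch_length(branch, root_stem_length)
            )
        return out


def dollo_reconstruct(
    tree: DatedTree, presence: Mapping[str, int]
) -> tuple[str, set[str]]:
    """Minimum-loss single-gain reconstruction of one presence vector.

    Returns ``(gain_branch, loss_branches)`` as branch labels; the gain is
    the stem above the MRCA of present leaves (``"root"`` when that MRCA is
    the root), losses are the stems of maximal all-absent subtrees below it.
    """
    present = {leaf for leaf, v in presence.items() if v == 1}
    if not present:
        raise ValueError("all-absent presence vector has no Dollo reconstruction")
    unknown = present - set(tree.leaf_names)
    if unknown:
        raise KeyError(f"species not in tree: {', '.join(sorted(unknown))}")

    mrca = tree.mrca(present)
    gain_branch = ROOT_BRANCH if mrca is tree.root else mrca.label

    losses: set[str] = set()

    def descend(node: TreeNode) -> None:
        for child in node.children:
            child_leaves = {l.label for l in child.leaves()}
            if child_leaves & present:
                descend(child)
            else:
                losses.add(child.label)  # maximal all-absent subtree

    descend(mrca)
    return gain_branch, losses


def count_gain_loss(
    tree: DatedTree, matrix: OrthogroupMatrix
) -> GainLossReconstruction:
    """Apply :func:`dollo_reconstruct` to every matrix row and aggregate.

    Rows whose present species all lie outside the tree's leaf set are
    skipped with a warning; species names present both in the matrix and
    the tree must agree exactly.
    """
    tree_leaves = set(tree.leaf_names)
    rec = GainLossReconstruction()
    rec.gains = {b: 0 for b in tree.branch_labels()}
    rec.losses = {b: 0 for b in tree.branch_labels()}
    for og_id in sorted(matrix.rows):
        row = matrix.rows[og_id]
        present = {sp for sp, v in row.items() if v == 1}
        in_tree = present & tree_leaves
        if not in_tree:
            logger.warning(
                "orthogroup %s present only outside the tree leaf set; skipped",
                og_id,
            )
            continue
        gain, losses = dollo_reconstruct(tree, {sp: 1 for sp in in_tree})
        rec.gain_branch[og_id] = gain
        rec.loss_branches[og_id] = losses
        rec.gains[gain] += 1
        for b in losses:
            rec.losses[b] += 1
    return rec


def net_rate(gains: int, losses: int, branch_length_myr: float) -> float:
    """Net gain rate per Myr: ``(gains - losses) / branch_length``."""
    if branch_length_myr <= 0:
        raise ValueError(f"branch length must be positive, got {branch_length_myr}")
    return (gains - losses) / branch_length_myr


def seed_family_turnover(
    tree: DatedTree, seed_presence: OrthogroupMatrix
) -> GainLossReconstruction:
    """Gain/loss reconstruction for seed families rather than orthogroups.

    Rows are keyed by 7-nt seed sequence; because presence is per seed, a
    species that loses one orthogroup but retains another carrying the same
    seed shows no loss for that seed row (loss compensation).
    """
    return count_gain_loss(tree, seed_presence)
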