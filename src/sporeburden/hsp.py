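"""Hidden state prediction of sporulation ability on a reference phylogeny.

The estimator is the empirical-probability variant of hidden state
prediction: the probability that an unlabeled tip is a spore-former is
the observed spore-former frequency among the labeled tips descending
from its nearest *informative* ancestor — the first node on the path
from the tip's parent toward the root that has at least one labeled
descendant other than the tip itself. The estimator uses topology only;
branch lengths never enter, so predictions are invariant to rescaling.

Evaluation is leave-one-out: each labeled tip is hidden in turn,
re-predicted, and the score sweep is summarized as average precision
(step-interpolated area under the precision-recall curve) with
spore-former as the positive class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import skbio
from Bio import Align

from .io import normalize_sequence

TraitTable = dict[str, bool]  # tip label -> spore_former; absent = unknown


@dataclass
class HSPResult:
    """Per-tip spore-former probabilities and thresholded labels."""

    predictions: pd.DataFrame   # index: tip; columns: probability, label, source_node
    threshold: float

    def probability(self, tip: str) -> float:
        return float(self.predictions.loc[tip, "probability"])

    def labels(self) -> pd.Series:
        return self.predictions["label"]


@dataclass
class LOOCVReport:
    """Leave-one-out evaluation of the empirical HSP estimator."""

    per_tip: pd.DataFrame       # index: tip; columns: true_state, probability
    curve: pd.DataFrame         # columns: recall, precision (tie groups)
    average_precision: float


# ---------------------------------------------------------------------------
# trait-table construction by exact sequence identity
# ---------------------------------------------------------------------------

def build_reference_traits(
    ref_sequences: dict[str, str],
    trait_records: pd.DataFrame,
) -> TraitTable:
    """Label reference tips by exact 16S identity with trait records.

    A record labels a tip iff the two sequences are identical after
    uppercasing and gap removal; a record matching several tips labels
    all of them. A tip hit by conflicting records takes the majority
    state; an exact tie leaves it unknown.

    ``trait_records`` needs columns ``sequence`` and ``spore_former``.
    """
    if trait_records.empty:
        raise ValueError("empty trait record set")
    if "sequence" not in trait_records.columns:
        raise ValueError("trait records need a 'sequence' column")
    by_seq: dict[str, list[str]] = {}
    for tip, seq in ref_sequences.items():
        by_seq.setdefault(normalize_sequence(seq), []).append(tip)
    votes: dict[str, list[bool]] = {}
    for _, rec in trait_records.iterrows():
        seq = normalize_sequence(rec["sequence"])
        for tip in by_seq.get(seq, ()):
            votes.setdefault(tip, []).append(bool(rec["spore_former"]))
    traits: TraitTable = {}
    for tip, states in votes.items():
        n_pos = sum(states)
        n_neg = len(states) - n_pos
        if n_pos != n_neg:
            traits[tip] = n_pos > n_neg
    return traits


# ---------------------------------------------------------------------------
# empirical state frequencies and the nearest-informative-ancestor rule
# ---------------------------------------------------------------------------

def _tally_known(tree: skbio.TreeNode, traits: TraitTable) -> None:
    """Annotate every node with (n_known, n_spore) over its labeled
    descendant tips, and every node with a stable generated name slot."""
    idx = 0
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            known = node.name in traits
            node._hsp_known = 1 if known else 0
            node._hsp_spore = 1 if known and traits[node.name] else 0
        else:
            node._hsp_known = sum(c._hsp_known for c in node.children)
            node._hsp_spore = sum(c._hsp_spore for c in node.children)
        if node.name is None:
            node._hsp_label = f"node{idx}"
        else:
            node._hsp_label = str(node.name)
        idx += 1


def node_state_frequencies(tree: skbio.TreeNode, traits: TraitTable) -> dict:
    """Spore-former frequency among labeled tips under every node.

    Returns a dict mapping each node (skbio TreeNode object) to
    f(v) = labeled spore-formers under v / labeled tips under v,
    omitting nodes with no labeled descendants.
    """
    if not traits:
        raise ValueError("at least one labeled tip is required")
    _tally_known(tree, traits)
    freqs: dict = {}
    for node in tree.postorder(include_self=True):
        if node._hsp_known > 0:
            freqs[node] = node._hsp_spore / node._hsp_known
    return freqs


def _predict_tip(tip: skbio.TreeNode, traits: TraitTable) -> tuple[float, str]:
    """Nearest-informative-ancestor probability for one tip, excluding
    the tip's own label (if any) from every count on the path."""
    excl_known = 1 if tip.name in traits else 0
    excl_spore = 1 if excl_known and traits[tip.name] else 0
    node = tip.parent
    while node is not None:
        n_known = node._hsp_known - excl_known
        if n_known > 0:
            n_spore = node._hsp_spore - excl_spore
            return n_spore / n_known, node._hsp_label
        node = node.parent
    raise ValueError(
        f"no informative ancestor for tip {tip.name!r}: no other labeled tips"
    )


def hsp_empirical(
    tree: skbio.TreeNode,
    traits: TraitTable,
    threshold: float = 0.5,
    targets: list[str] | None = None,
) -> HSPResult:
    """Predict spore-former probabilities for unlabeled tips.

    ``targets`` defaults to every tip absent from ``traits``. The
    predicted label is spore_former iff probability >= ``threshold``
    (ties go to the positive class — conservative for planetary
    protection purposes).
    """
    if not traits:
        raise ValueError("at least one labeled tip is required")
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    _tally_known(tree, traits)
    tips = {t.name: t for t in tree.tips()}
    unknown_labels = set(traits) - set(tips)
    if unknown_labels:
        raise ValueError(f"trait labels not on the tree: {sorted(unknown_labels)[:5]}")
    if targets is None:
        targets = [name for name in tips if name not in traits]
    rows = {}
    for name in targets:
        prob, source = _predict_tip(tips[name], traits)
        rows[name] = (prob, prob >= threshold, source)
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=["probability", "label", "source_node"]
    )
    df["label"] = df["label"].astype(bool)
    return HSPResult(predictions=df, threshold=threshold)


# ---------------------------------------------------------------------------
# leave-one-out cross-validation and average precision
# ---------------------------------------------------------------------------

def average_precision(y_true, scores) -> tuple[float, pd.DataFrame]:
    """Step-interpolated area under the precision-recall curve.

    Scores are swept in descending order; tied scores are processed as a
    single group. AP = sum over groups of (R_k - R_{k-1}) * P_k. Returns
    (AP, curve DataFrame with one row per tie group).
    """
    y = np.asarray(y_true, dtype=bool)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    if n_pos == 0 or n_pos == len(y):
        raise ValueError("average precision needs both classes present")
    order = np.argsort(-s, kind="stable")
    y, s = y[order], s[order]
    ap = 0.0
    tp = 0
    n_seen = 0
    prev_recall = 0.0
    rows = []
    i = 0
    while i < len(s):
        j = i
        while j < len(s) and s[j] == s[i]:
            j += 1
        tp += int(y[i:j].sum())
        n_seen = j
        precision = tp / n_seen
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        rows.append((s[i], recall, precision))
        prev_recall = recall
        i = j
    curve = pd.DataFrame(rows, columns=["score", "recall", "precision"])
    return ap, curve


def loocv_average_precision(tree: skbio.TreeNode, traits: TraitTable) -> LOOCVReport:
    """Hold out each labeled tip, re-predict it, and summarize as AP.

    Because `_predict_tip` always excludes the focal tip's own label
    from every ancestor count, one global tally suffices: the held-out
    prediction never sees its own state.
    """
    if len(traits) < 2:
        raise ValueError("LOOCV needs at least two labeled tips")
    states = set(traits.values())
    if len(states) < 2:
        raise ValueError("LOOCV needs both states represented")
    _tally_known(tree, traits)
    tips = {t.name: t for t in tree.tips()}
    rows = {}
    for name, state in traits.items():
        prob, _ = _predict_tip(tips[name], traits)
        rows[name] = (state, prob)
    per_tip = pd.DataFrame.from_dict(
        rows, orient="index", columns=["true_state", "probability"]
    )
    ap, curve = average_precision(per_tip["true_state"], per_tip["probability"])
    return LOOCVReport(per_tip=per_tip, curve=curve, average_precision=ap)


# ---------------------------------------------------------------------------
# query placement by best-hit p-distance
# ---------------------------------------------------------------------------

def _p_distance_aligned(a: str, b: str) -> float:
    both = [(x, y) for x, y in zip(a, b) if x not in "-." and y not in "-."]
    if not both:
        raise ValueError("no comparable positions between sequences")
    mismatches = sum(x != y for x, y in both)
    return mismatches / len(both)


def _p_distance_raw(aligner: Align.PairwiseAligner, a: str, b: str) -> float:
    aln = aligner.align(a, b)[0]
    overlap = 0
    mismatches = 0
    for (a_start, a_end), (b_start, b_end) in zip(*aln.aligned):
        overlap += a_end - a_start
        seg_a = a[a_start:a_end]
        seg_b = b[b_start:b_end]
        mismatches += sum(x != y for x, y in zip(seg_a, seg_b))
    if overlap == 0:
        raise ValueError("no comparable positions between sequences")
    return mismatches / overlap


def place_queries(
    tree: skbio.TreeNode,
    ref_sequences: dict[str, str],
    query_sequences: dict[str, str],
) -> skbio.TreeNode:
    """Attach each query as a sibling of its closest reference tip.

    Distance is the normalized p-distance over the pairwise-overlapping
    positions: positional comparison when sequences arrive pre-aligned
    (all equal length), otherwise over a unit-score global alignment.
    Ties go to the lexicographically smallest tip label. The pendant
    branch length is the p-distance (0 for an identical sequence); a new
    zero-effect internal node carries the reference tip's original
    branch length, so distances between pre-existing tips are unchanged.
    """
    if not query_sequences:
        raise ValueError("empty query set")
    tip_names = {t.name for t in tree.tips()}
    usable = {k: v for k, v in ref_sequences.items() if k in tip_names}
    if not usable:
        raise ValueError("no reference sequences match tree tips")
    lengths = {len(s) for s in usable.values()} | {
        len(s) for s in query_sequences.values()
    }
    prealigned = len(lengths) == 1
    aligner = None
    if not prealigned:
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1.0
        aligner.mismatch_score = 0.0
        aligner.open_gap_score = 0.0
        aligner.extend_gap_score = 0.0
        usable = {k: normalize_sequence(v) for k, v in usable.items()}
        query_sequences = {
            k: normalize_sequence(v) for k, v in query_sequences.items()
        }

    out = tree.copy()
    ref_order = sorted(usable)
    for qname, qseq in query_sequences.items():
        best_tip, best_d = None, np.inf
        for rname in ref_order:
            rseq = usable[rname]
            d = (_p_distance_aligned(rseq, qseq) if prealigned
                 else _p_distance_raw(aligner, rseq, qseq))
            if d < best_d:  # ref_order sorted, so first hit wins ties
                best_tip, best_d = rname, d
        anchor = out.find(best_tip)
        parent = anchor.parent
        new_internal = skbio.TreeNode(length=anchor.length)
        parent.remove(anchor)
        anchor.length = 0.0
        query_tip = skbio.TreeNode(name=qname, length=float(best_d))
        new_internal.extend([anchor, query_tip])
        parent.append(new_internal)
    return out
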