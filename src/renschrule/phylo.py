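"""Newick trees, ancestral values and phylogenetically independent contrasts.

Trees are handled as :class:`dendropy.Tree` objects (the module-level
alias ``PhyloTree`` points there).  Contrast computation is a single
post-order pass implementing Felsenstein's pruning recursion: at each
internal node with daughters carrying (value, branch length) pairs
(x1, v1) and (x2, v2),

* the contrast is x1 - x2, standardized by sqrt(v1 + v2);
* the node's ancestral value is either the branch-length-weighted mean
  (x1/v1 + x2/v2) / (1/v1 + 1/v2) (``felsenstein_weighted``) or the plain
  mean (x1 + x2)/2 (``algebraic_mean``);
* the node's own branch length is lengthened to v + v1·v2/(v1 + v2) to
  absorb the uncertainty of the ancestral estimate.

``algebraic_mean`` changes only the ancestral value estimate; the
branch-length bookkeeping (and hence the standardization divisors) is the
same in both methods.  Edges without a stated length are given unit
length, so on a length-free tree every cherry contrast is divided by √2.

An N-tip strictly bifurcating tree yields N-1 contrasts, statistically
independent under Brownian trait evolution.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import dendropy
import numpy as np

from ._errors import (
    FormatError,
    InsufficientDataError,
    MismatchError,
    UnsupportedTopologyError,
    ValidationError,
)
from .table_io import TraitTable

logger = logging.getLogger(__name__)

PhyloTree = dendropy.Tree

METHODS = ("algebraic_mean", "felsenstein_weighted")
DEFAULT_METHOD = "algebraic_mean"


@dataclass(frozen=True)
class Contrast:
    """One internal node's paired trait contrasts.

    ``tips`` lists the descendant tip labels (sorted) — a stable node
    identifier across tree implementations.  ``scale`` is the standard
    deviation divisor sqrt(v1 + v2); it is recorded even for raw
    (unstandardized) contrasts.
    """

    node_id: str
    tips: tuple[str, ...]
    contrast_x: float
    contrast_y: float
    scale: float


@dataclass
class ContrastSet:
    """N-1 paired contrasts for two traits on one bifurcating tree."""

    contrasts: list[Contrast]
    method: str
    standardized: bool

    def __len__(self) -> int:
        return len(self.contrasts)

    def __iter__(self):
        return iter(self.contrasts)

    @property
    def x(self) -> np.ndarray:
        return np.array([c.contrast_x for c in self.contrasts], dtype=float)

    @property
    def y(self) -> np.ndarray:
        return np.array([c.contrast_y for c in self.contrasts], dtype=float)

    @property
    def scales(self) -> np.ndarray:
        return np.array([c.scale for c in self.contrasts], dtype=float)


@dataclass
class StandardizationReport:
    """Adequacy diagnostic: |standardized contrast| vs its SD divisor.

    Under correct standardization the magnitude of a contrast is
    independent of its divisor; a significant positive correlation means
    branch lengths understate the variance of divergence (and vice
    versa).  ``passed`` = neither trait shows a correlation at α = 0.05.
    """

    r_x: float
    p_x: float
    r_y: float
    p_y: float
    n: int
    alpha: float = 0.05
    passed: bool = field(init=False)

    def __post_init__(self) -> None:
        self.passed = self.p_x >= self.alpha and self.p_y >= self.alpha


def read_newick(source: str | Path) -> PhyloTree:
    """Read a rooted Newick tree from a file path or a literal string.

    Child order is preserved and missing branch lengths stay ``None``
    (they are not silently zeroed).  Duplicate tip labels are rejected.
    """
    text = str(source)
    if "(" not in text:  # no Newick structure: treat as a path
        text = Path(source).read_text(encoding="utf-8")
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"cannot parse Newick input: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = {name for name in labels if labels.count(name) > 1}
    if dupes:
        raise FormatError(f"duplicate tip labels: {sorted(dupes)}")
    return tree


def write_newick(tree: PhyloTree, path: str | Path | None = None) -> str:
    """Serialize a tree to Newick; write to ``path`` when given."""
    text = tree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True
    ).strip()
    if path is not None:
        Path(path).write_text(text + "\n", encoding="utf-8")
    return text


def _node_tips(node: dendropy.Node) -> tuple[str, ...]:
    return tuple(sorted(leaf.taxon.label for leaf in node.leaf_iter()))


def _edge_length(node: dendropy.Node) -> float:
    length = node.edge.length
    if length is None:
        return 1.0
    if length < 0:
        raise ValidationError(f"negative branch length {length} on {node}")
    return float(length)


def _pic_pass(
    tree: PhyloTree,
    tip_x: Mapping[str, float],
    tip_y: Mapping[str, float] | None,
    method: str,
) -> tuple[list[dict], dict[frozenset, dict[str, float]]]:
    """Single post-order pruning pass over both traits.

    Returns per-internal-node contrast records (post-order) and the
    ancestral value estimates keyed by frozenset of descendant tips.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    traits = ["x"] if tip_y is None else ["x", "y"]
    tip_maps = {"x": tip_x, "y": tip_y}

    # per-node working state: estimated value per trait + adjusted length
    value: dict[dendropy.Node, dict[str, float]] = {}
    adj_len: dict[dendropy.Node, float] = {}
    contrasts: list[dict] = []
    ancestral: dict[frozenset, dict[str, float]] = {}

    for idx, node in enumerate(tree.postorder_node_iter(), start=1):
        if node.is_leaf():
            label = node.taxon.label if node.taxon else None
            if label is None:
                raise ValidationError("tree contains an unlabeled tip")
            vals = {}
            for t in traits:
                try:
                    vals[t] = float(tip_maps[t][label])  # type: ignore[index]
                except KeyError:
                    raise ValidationError(f"no trait value for tip {label!r}")
            value[node] = vals
            adj_len[node] = _edge_length(node)
            continue
        children = node.child_nodes()
        if len(children) != 2:
            raise UnsupportedTopologyError(
                f"node with {len(children)} children; contrasts require a "
                "strictly bifurcating tree"
            )
        c1, c2 = children
        v1, v2 = adj_len[c1], adj_len[c2]
        scale = float(np.sqrt(v1 + v2))
        rec: dict = {
            "node_id": f"n{idx}",
            "tips": _node_tips(node),
            "scale": scale,
        }
        vals = {}
        for t in traits:
            x1, x2 = value[c1][t], value[c2][t]
            rec[f"contrast_{t}"] = x1 - x2
            if method == "felsenstein_weighted":
                vals[t] = (x1 / v1 + x2 / v2) / (1.0 / v1 + 1.0 / v2)
            else:
                vals[t] = 0.5 * (x1 + x2)
        value[node] = vals
        adj_len[node] = _edge_length(node) + v1 * v2 / (v1 + v2)
        contrasts.append(rec)
        ancestral[frozenset(rec["tips"])] = dict(vals)
    return contrasts, ancestral


def ancestral_values(
    tree: PhyloTree,
    tip_values: Mapping[str, float],
    method: str = DEFAULT_METHOD,
) -> dict[frozenset, float]:
    """Ancestral node estimates, keyed by frozenset of descendant tip labels.

    ``algebraic_mean`` averages the two daughter values unweighted;
    ``felsenstein_weighted`` weights them by inverse adjusted branch
    length (equal branches reduce to the plain mean).
    """
    _, anc = _pic_pass(tree, tip_values, None, method)
    return {key: vals["x"] for key, vals in anc.items()}


def compute_contrasts(
    tree: PhyloTree,
    tip_x: Mapping[str, float],
    tip_y: Mapping[str, float],
    method: str = DEFAULT_METHOD,
    standardize: bool = True,
) -> ContrastSet:
    """Paired independent contrasts of two traits on one tree.

    Both traits share the node pairing and daughter ordering (tree child
    order), so their contrast signs are coupled.  ``standardize=True``
    divides each contrast by sqrt of the summed adjusted daughter branch
    lengths; raw differences are returned otherwise, with the divisor
    still recorded in ``scale``.
    """
    recs, _ = _pic_pass(tree, tip_x, tip_y, method)
    out = []
    for rec in recs:
        div = rec["scale"] if standardize else 1.0
        out.append(
            Contrast(
                node_id=rec["node_id"],
                tips=rec["tips"],
                contrast_x=rec["contrast_x"] / div,
                contrast_y=rec["contrast_y"] / div,
                scale=rec["scale"],
            )
        )
    return ContrastSet(contrasts=out, method=method, standardized=standardize)


def standardization_check(contrasts: ContrastSet) -> StandardizationReport:
    """Correlate |standardized contrast| with its SD divisor, per trait."""
    from scipy import stats

    if not contrasts.standardized:
        raise ValueError("standardization_check requires standardized contrasts")
    n = len(contrasts)
    if n < 3:
        raise InsufficientDataError(f"need at least 3 contrasts, got {n}")
    scales = contrasts.scales
    if np.ptp(scales) == 0.0:
        # equal divisors everywhere: correlation undefined, trivially adequate
        return StandardizationReport(r_x=0.0, p_x=1.0, r_y=0.0, p_y=1.0, n=n)
    r_x, p_x = stats.pearsonr(np.abs(contrasts.x), scales)
    r_y, p_y = stats.pearsonr(np.abs(contrasts.y), scales)
    return StandardizationReport(
        r_x=float(r_x), p_x=float(p_x), r_y=float(r_y), p_y=float(p_y), n=n
    )


def prune_and_align(
    tree: PhyloTree, table: TraitTable
) -> tuple[PhyloTree, TraitTable]:
    """Reduce tree and table to their shared species, in tip order.

    Degree-2 nodes created by pruning are suppressed with branch lengths
    summed.  Species dropped from either side are logged.
    """
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    names = set(table.species)
    shared = tips & names
    if not shared:
        raise MismatchError(
            "tree tips and table species share no names; check label conventions"
        )
    dropped_tips = sorted(tips - shared)
    dropped_rows = sorted(names - shared)
    if dropped_tips:
        logger.info("pruning %d tip(s) absent from table: %s", len(dropped_tips), dropped_tips)
    if dropped_rows:
        logger.info("dropping %d species absent from tree: %s", len(dropped_rows), dropped_rows)
    pruned = tree.extract_tree_with_taxa_labels(labels=shared)
    tip_order = [leaf.taxon.label for leaf in pruned.leaf_node_iter()]
    by_name = {rec.species: rec for rec in table}
    aligned = TraitTable(
        records=[by_name[name] for name in tip_order],
        provenance=table.provenance,
    )
    return pruned, aligned
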