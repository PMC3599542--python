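"""Independent brute-force reference implementations used only by tests.

The contrast oracle is a direct recursive transcription of the textbook
pruning algorithm, deliberately written apart from the package's
iterative post-order implementation.
"""
from __future__ import annotations

import math


def pic_recursive(node, tip_values, method, default_length=1.0):
    """Return (est_value, adjusted_length, contrasts) for a dendropy node.

    ``contrasts`` is a list of dicts with keys tips, raw, standardized,
    scale, collected bottom-up.  ``method`` is 'algebraic_mean' or
    'felsenstein_weighted'.
    """
    length = node.edge.length if node.edge.length is not None else default_length
    children = node.child_nodes()
    if not children:
        return tip_values[node.taxon.label], length, []
    assert len(children) == 2, "oracle requires a bifurcating tree"
    xl, vl, cl = pic_recursive(children[0], tip_values, method, default_length)
    xr, vr, cr = pic_recursive(children[1], tip_values, method, default_length)
    raw = xl - xr
    scale = math.sqrt(vl + vr)
    if method == "felsenstein_weighted":
        value = (xl / vl + xr / vr) / (1.0 / vl + 1.0 / vr)
    else:
        value = (xl + xr) / 2.0
    tips = frozenset(
        leaf.taxon.label for leaf in node.leaf_iter()
    )
    contrasts = cl + cr + [
        {"tips": tips, "raw": raw, "standardized": raw / scale, "scale": scale}
    ]
    return value, length + vl * vr / (vl + vr), contrasts


def pic_oracle(tree, tip_values, method):
    """All contrasts of a tree as {tips_frozenset: record}."""
    _, _, contrasts = pic_recursive(tree.seed_node, tip_values, method)
    return {c["tips"]: c for c in contrasts}
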