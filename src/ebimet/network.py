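"""Reaction-based biotransformation networks over cohort feature tables.

For each parent xenobiotic feature, features whose intensity profiles are
associated with the parent across samples (|r| above a threshold, default
0.4) are candidate related metabolites; a mass-difference filter
(m/z_feature − m/z_parent against a table of biotransformation and
adduct/isotope deltas) then keeps only edges explainable by a known reaction
or ionization artifact.  The union of per-parent stars forms the network;
with distinct exposure patterns each parent's pathway falls into its own
connected component.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .chem import TransformationRule, ppm_error
from .io import FeatureTable

__all__ = ["NetworkEdge", "associate", "mass_shift_edges", "build_network"]


@dataclass(frozen=True)
class NetworkEdge:
    parent_feature_id: str
    child_feature_id: str
    association_r: float
    delta_mz: float  # child - parent
    matched_rule: TransformationRule
    direction: int  # +1: rule delta added to parent; -1: subtracted
    ppm_error_of_delta: float


def _association_scores(
    parent_feature_id: str, table: FeatureTable, method: str
) -> dict[str, float]:
    mat = table.intensity_matrix(0.0)
    if parent_feature_id not in mat.index:
        raise KeyError(f"parent feature {parent_feature_id!r} not in table")
    y = mat.loc[parent_feature_id].to_numpy(dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 samples")
    if np.std(y) == 0:
        raise ValueError("parent feature has zero intensity variance")
    x = mat.to_numpy(dtype=float)
    yc = (y - y.mean()) / y.std()
    sd = x.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        xc = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
        r = (xc @ yc) / len(y)
    # For a single parent response, the first PLS component weights are
    # proportional to X^T y on standardized data, i.e. the association
    # ordering coincides with Pearson correlation; "pls1" therefore reports
    # the same scores and exists to name the intent.
    if method not in ("pearson", "pls1"):
        raise ValueError(f"unknown association method {method!r}")
    r = np.where(np.isfinite(r), r, 0.0)  # zero-variance children: no signal
    return {fid: float(ri) for fid, ri in zip(mat.index, r)}


def associate(
    parent_feature_id: str,
    table: FeatureTable,
    method: str = "pearson",
    r_threshold: float = 0.4,
) -> list[tuple[str, float]]:
    """Features associated with the parent's intensity profile.

    Missing intensities are treated as zero (not detected).  Returns
    (feature_id, r) for |r| > ``r_threshold``, the parent excluded, sorted by
    descending |r|.
    """
    scores = _association_scores(parent_feature_id, table, method)
    out = [
        (fid, r)
        for fid, r in scores.items()
        if fid != parent_feature_id and abs(r) > r_threshold
    ]
    out.sort(key=lambda t: -abs(t[1]))
    return out


def mass_shift_edges(
    parent_feature_id: str,
    associated: Sequence[tuple[str, float]],
    table: FeatureTable,
    rules: Sequence[TransformationRule],
    ppm_tol: float = 3.0,
    max_abs_delta: float | None = None,
) -> list[NetworkEdge]:
    """Keep associated features whose mass offset matches a known delta.

    The observed child − parent m/z difference is compared against each
    rule's mass shift, within ``ppm_tol`` evaluated on the child m/z.
    Biotransformation deltas are applied with their chemical sign only
    (a glucuronide is heavier than its parent, a demethylation product
    lighter); adduct/isotope spacings are tried in both directions.  The
    best-matching rule (smallest |ppm|) annotates each edge.
    """
    mz_p = table.mz(parent_feature_id)
    edges: list[NetworkEdge] = []
    for fid, r in associated:
        mz_c = table.mz(fid)
        delta = mz_c - mz_p
        if max_abs_delta is not None and abs(delta) > max_abs_delta:
            continue
        best: NetworkEdge | None = None
        for rule in rules:
            directions = (
                (+1, -1) if rule.phase == "adduct/isotope" else (+1,)
            )
            for sign in directions:
                expected = mz_p + sign * rule.mass_delta
                if expected <= 0:
                    continue
                err = ppm_error(mz_c, expected)
                if abs(err) > ppm_tol:
                    continue
                cand = NetworkEdge(
                    parent_feature_id, fid, r, delta, rule, sign, err
                )
                if best is None or abs(cand.ppm_error_of_delta) < abs(
                    best.ppm_error_of_delta
                ):
                    best = cand
        if best is not None:
            edges.append(best)
    return edges


def build_network(
    parents: Mapping[str, str],
    table: FeatureTable,
    rules: Sequence[TransformationRule],
    r_threshold: float = 0.4,
    ppm_tol: float = 3.0,
    method: str = "pearson",
    annotations: Mapping[str, str] | None = None,
) -> nx.Graph:
    """Union of per-parent biotransformation stars as a networkx graph.

    ``parents`` maps parent compound name → its feature id in the table.
    Nodes carry mz/rt/annotation attributes; edges carry the matched rule
    name, mass delta and association r.  Nodes reached from more than one
    parent are flagged ``ambiguous``.  Connected components of the result are
    the pathway-level clusters.
    """
    g = nx.Graph()
    annotations = annotations or {}
    reached_by: dict[str, set[str]] = {}
    for parent_name, fid in parents.items():
        if fid not in table.features.index:
            raise KeyError(f"parent feature {fid!r} absent from table")
        g.add_node(
            fid,
            mz=table.mz(fid),
            rt=table.rt(fid),
            annotation=annotations.get(fid, parent_name),
            role="parent",
        )
        assoc = associate(fid, table, method=method, r_threshold=r_threshold)
        for edge in mass_shift_edges(fid, assoc, table, rules, ppm_tol=ppm_tol):
            child = edge.child_feature_id
            if child not in g:
                g.add_node(
                    child,
                    mz=table.mz(child),
                    rt=table.rt(child),
                    annotation=annotations.get(child, ""),
                    role="metabolite",
                )
            g.add_edge(
                fid,
                child,
                rule=edge.matched_rule.name,
                phase=edge.matched_rule.phase,
                delta_mz=edge.delta_mz,
                r=edge.association_r,
                ppm=edge.ppm_error_of_delta,
            )
            reached_by.setdefault(child, set()).add(parent_name)
    for node, sources in reached_by.items():
        g.nodes[node]["ambiguous"] = len(sources) > 1
    return g
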