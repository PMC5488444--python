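"""Taxon-by-family locus counts and the phylogenetic regression.

``build_counts`` joins per-taxon locus sets to life-history labels;
``summarize_groups`` reproduces integer-truncated group means; ``pgls_fit``
is generalized least squares under a Brownian-motion tree covariance
(C[i,j] = shared root-to-MRCA path length), with a nested-model F test for
the life-history term.
"""

from __future__ import annotations

import csv
import logging
import math
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import stats

from .coalesce import LocusSet

logger = logging.getLogger(__name__)

LIFE_HISTORIES = ("galling", "free_living", "inquiline")

#: group definitions used for the published-table style summaries
DEFAULT_GROUPS = {
    "galling": ("galling", "inquiline"),
    "free_living": ("free_living",),
}

#: life-history contrast used by default in the regression
DEFAULT_CODING = {"galling": 0.0, "inquiline": 0.0, "free_living": 1.0}


def read_life_history(path) -> dict[str, str]:
    """TSV (taxon, life_history) -> dict; a header row is optional."""
    table: dict[str, str] = {}
    with open(path) as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 2:
                raise ValueError(f"{path}: row {lineno}: expected 2 columns")
            if lineno == 1 and row[0].lower() == "taxon":
                continue
            table[row[0]] = row[1]
    return table


def build_counts(
    locus_sets: Iterable[LocusSet],
    life_history: Mapping[str, str],
    families: Sequence[str] = ("APC", "AAAP"),
) -> pd.DataFrame:
    """One row per taxon: per-family locus counts, their total, and the label.

    Counting is family-agnostic — any family named in ``families`` gets a
    column (lower-cased); families absent from the locus sets count 0.
    """
    counts: dict[str, dict[str, int]] = {}
    for ls in locus_sets:
        if ls.family not in families:
            logger.info("ignoring locus set for unlisted family %s", ls.family)
            continue
        row = counts.setdefault(ls.taxon, {f: 0 for f in families})
        row[ls.family] += ls.count
    rows = []
    for taxon in sorted(counts):
        if taxon not in life_history:
            raise KeyError(f"taxon {taxon!r} has no life-history label")
        rec = {"taxon": taxon}
        rec.update({f.lower(): counts[taxon][f] for f in families})
        rec["total"] = sum(counts[taxon].values())
        rec["life_history"] = life_history[taxon]
        rows.append(rec)
    cols = ["taxon", *[f.lower() for f in families], "total", "life_history"]
    return pd.DataFrame(rows, columns=cols)


def summarize_groups(
    counts: pd.DataFrame, groups: Mapping[str, Sequence[str]] = DEFAULT_GROUPS
) -> pd.DataFrame:
    """Per-group arithmetic means truncated toward zero.

    The total column of the summary is the sum of the truncated per-family
    means, not the truncated mean of the totals.
    """
    value_cols = [c for c in counts.columns if c not in ("taxon", "life_history", "total")]
    out = []
    for name, labels in groups.items():
        sub = counts[counts["life_history"].isin(labels)]
        if sub.empty:
            raise ValueError(f"group {name!r} matches no taxa")
        rec = {"group": name, "n": len(sub)}
        for col in value_cols:
            rec[col] = math.trunc(sub[col].mean())
        rec["total"] = sum(rec[col] for col in value_cols)
        out.append(rec)
    return pd.DataFrame(out, columns=["group", "n", *value_cols, "total"])


# ---------------------------------------------------------------------------
# Trees and the Brownian covariance


def read_newick(path, default_branch_length: float = 1.0) -> dendropy.Tree:
    """Parse a Newick tree; missing branch lengths get a warned default."""
    tree = dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )
    patched = 0
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            edge.length = default_branch_length
            patched += 1
        elif edge.length < 0:
            raise ValueError("negative branch length in tree")
    if patched:
        warnings.warn(
            f"{patched} branch(es) lacked a length; defaulted to "
            f"{default_branch_length}"
        )
    return tree


def parse_newick(newick: str, **kwargs) -> dendropy.Tree:
    tree = dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )
    return tree


def brownian_vcv(tree: dendropy.Tree, taxa_order: Sequence[str]) -> np.ndarray:
    """Brownian-motion covariance: shared root-to-MRCA path lengths.

    Diagonal entries are root-to-tip distances; off-diagonals the depth of
    the most recent common ancestor.
    """
    tips = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
    missing = [t for t in taxa_order if t not in tips]
    if missing:
        raise KeyError(f"taxa not in tree: {missing}")
    # root-to-node depth for every node
    depth: dict[int, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depth[id(node)] = 0.0
        else:
            depth[id(node)] = depth[id(node.parent_node)] + (node.edge.length or 0.0)
    # ancestor chains per tip
    chains: dict[str, list] = {}
    for label in taxa_order:
        chain = []
        node = tips[label]
        while node is not None:
            chain.append(id(node))
            node = node.parent_node
        chains[label] = chain
    n = len(taxa_order)
    C = np.zeros((n, n))
    for i, a in enumerate(taxa_order):
        set_a = set(chains[a])
        C[i, i] = depth[chains[a][0]]
        for j in range(i + 1, n):
            b = taxa_order[j]
            mrca = next(nid for nid in chains[b] if nid in set_a)
            C[i, j] = C[j, i] = depth[mrca]
    return C


# ---------------------------------------------------------------------------
# PGLS


@dataclass(frozen=True)
class PGLSResult:
    beta: np.ndarray  # (intercept, contrast coefficients...)
    sigma2: float  # residual Brownian rate estimate
    F: float
    df: tuple[int, int]
    p: float


def pgls_fit(
    y: Sequence[float],
    x: Sequence[float],
    C: np.ndarray,
    ridge: float = 1e-8,
) -> PGLSResult:
    """GLS of y on (1, x) with error covariance proportional to C.

    Fitting whitens by the Cholesky factor of C; the F statistic compares
    the full model against intercept-only:
    F = ((RSS0 - RSS1)/q) / (RSS1/(n - p)).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n = y.shape[0]
    if n < 3:
        raise ValueError("need at least 3 observations")
    if x.shape[0] != n or C.shape != (n, n):
        raise ValueError("shape mismatch between y, x, and C")
    X = np.column_stack([np.ones(n), x])
    p = X.shape[1]
    q = p - 1
    if np.linalg.matrix_rank(X) < p:
        raise ValueError(
            "singular design: the life-history contrast is constant across taxa"
        )
    L = None
    for attempt in range(3):
        try:
            L = sla.cholesky(C, lower=True)
            break
        except sla.LinAlgError:
            bump = ridge * (10.0**attempt) * np.trace(C) / n
            warnings.warn(
                f"covariance not positive definite; adding ridge {bump:g}"
            )
            C = C + bump * np.eye(n)
    if L is None:
        raise sla.LinAlgError("covariance matrix not positive definite")
    z = sla.solve_triangular(L, y, lower=True)
    W = sla.solve_triangular(L, X, lower=True)
    beta, *_ = np.linalg.lstsq(W, z, rcond=None)
    rss1 = float(np.sum((z - W @ beta) ** 2))
    beta0, *_ = np.linalg.lstsq(W[:, :1], z, rcond=None)
    rss0 = float(np.sum((z - W[:, :1] @ beta0) ** 2))
    sigma2 = rss1 / (n - p)
    scale = max(float(z @ z), 1.0)
    if rss1 <= 1e-13 * scale:
        if rss0 - rss1 <= 1e-13 * scale:
            F, pval = 0.0, 1.0
        else:
            F, pval = float("inf"), 0.0
    else:
        F = max(((rss0 - rss1) / q) / (rss1 / (n - p)), 0.0)
        pval = float(stats.f.sf(F, q, n - p))
    return PGLSResult(beta=beta, sigma2=sigma2, F=F, df=(q, n - p), p=pval)


def pgls_counts(
    counts: pd.DataFrame,
    tree: dendropy.Tree,
    response: str = "total",
    coding: Mapping[str, float] = DEFAULT_CODING,
) -> PGLSResult:
    """Fit response-column counts against the life-history contrast."""
    taxa = list(counts["taxon"])
    C = brownian_vcv(tree, taxa)
    x = np.array([coding[lh] for lh in counts["life_history"]])
    y = counts[response].to_numpy(dtype=float)
    return pgls_fit(y, x, C)


# ---------------------------------------------------------------------------
# Packaged fixtures


def load_published_counts(ingroup_only: bool = False) -> pd.DataFrame:
    """Published per-taxon APC/AAAP locus counts bundled with the package."""
    with resources.files("aatcensus").joinpath("data/aat_counts_published.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    if ingroup_only:
        df = df[df["clade"] == "ingroup"].reset_index(drop=True)
    return df


def load_species_topology() -> dendropy.Tree:
    """Unit-branch-length topology for the taxa of the published counts."""
    text = (
        resources.files("aatcensus").joinpath("data/species_topology.nwk").read_text()
    )
    return parse_newick(text)


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index=False)


def read_counts(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
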