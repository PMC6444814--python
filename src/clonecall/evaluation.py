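"""Scoring against simulator truth, clone clustering, implausibility FDR.

Two simulated experiments are scored.  Experiment 1 asks whether each locus
was detected as a *clonal* sSNV (called mutated in at least two cells);
sensitivity, specificity and FDR follow from the per-locus confusion
counts.  Experiment 2 scores genotype predictions per (cell, locus) in
sSNV-only simulations.  Independently of truth, cells can be clustered
from shared calls, and on real-style data with known clone labels an FDR
can be estimated from biologically implausible genotype distributions
(variants recurring in two unrelated clones).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from clonecall.formats import GenotypeState, SiteTable
from clonecall.simulator import TruthTable

log = logging.getLogger(__name__)

MUTATED = "mutated"
UNMUTATED = "unmutated"


@dataclass(frozen=True)
class ClonalConfusion:
    """Per-locus confusion counts of clonal sSNV detection (experiment 1)."""

    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0
    unmatched_calls: int = 0  # passing calls at positions outside the locus set

    @property
    def sensitivity(self) -> float | None:
        return None if self.tp + self.fn == 0 else self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float | None:
        return None if self.tn + self.fp == 0 else self.tn / (self.tn + self.fp)

    @property
    def fdr(self) -> float | None:
        return None if self.fp + self.tp == 0 else self.fp / (self.fp + self.tp)


@dataclass(frozen=True)
class GenotypeConfusion:
    """Per-(cell, locus) genotype prediction counts (experiment 2)."""

    true_het: int = 0
    false_het: int = 0
    true_hom: int = 0
    false_hom: int = 0
    no_prediction_het: int = 0
    no_prediction_hom: int = 0


def metrics(c: ClonalConfusion) -> dict[str, float | None]:
    """Sensitivity TP/(TP+FN), specificity TN/(TN+FP), FDR FP/(FP+TP).

    A 0/0 ratio is reported as None (missing), never coerced to 0 or 1.
    """
    return {"sensitivity": c.sensitivity, "specificity": c.specificity, "fdr": c.fdr}


def classify_clonal_calls(
    calls: SiteTable, truth: TruthTable, min_cells: int = 2
) -> ClonalConfusion:
    """Score each truth locus as TP/TN/FP/FN under the >=2-cells rule.

    A locus is *predicted* when a passing call at its sSNV position is
    mutated in at least ``min_cells`` cells.  Calls at positions matching
    no locus are tallied separately (and are false by construction).
    """
    by_site = truth.locus_by_site()
    predicted: set[int] = set()
    unmatched = 0
    for site in calls:
        locus = by_site.get(site.key)
        if locus is None:
            unmatched += 1
            continue
        if site.n_mutated >= min_cells:
            predicted.add(locus.locus_id)
    tp = tn = fp = fn = 0
    for locus in truth.loci:
        if locus.snv == 1:
            if locus.locus_id in predicted:
                tp += 1
            else:
                fn += 1
        else:
            if locus.locus_id in predicted:
                fp += 1
            else:
                tn += 1
    return ClonalConfusion(tp=tp, tn=tn, fp=fp, fn=fn, unmatched_calls=unmatched)


def genotype_confusion(calls: SiteTable, truth: TruthTable) -> GenotypeConfusion:
    """Bin every (cell, sSNV locus) into the six genotype-accuracy classes.

    Conflicts and absent/abstained calls count as no-prediction for the
    cell's true genotype class.
    """
    by_site = {site.key: site for site in calls}
    th = fh = tm = fm = nph = npm = 0
    for locus in truth.loci:
        if locus.snv != 1:
            continue
        site = by_site.get((locus.contig, locus.s_pos))
        for cell in truth.cells:
            true_gt = truth.true_genotype(cell, locus)
            state = site.genotypes.get(cell, GenotypeState.NONE) if site else GenotypeState.NONE
            if state.is_mutated:
                if true_gt == "het":
                    th += 1
                else:
                    fh += 1
            elif state.is_unmutated:
                if true_gt == "hom":
                    tm += 1
                else:
                    fm += 1
            else:
                if true_gt == "het":
                    nph += 1
                else:
                    npm += 1
    return GenotypeConfusion(
        true_het=th, false_het=fh, true_hom=tm, false_hom=fm,
        no_prediction_het=nph, no_prediction_hom=npm,
    )


def genotype_matrix(calls: SiteTable) -> pd.DataFrame:
    """Cells x sites matrix with entries 'mutated'/'unmutated'/NaN.

    Conflict and none states both map to unknown (NaN).
    """
    cols = {}
    for site in calls:
        col = []
        for s in calls.samples:
            state = site.genotypes.get(s, GenotypeState.NONE)
            col.append(
                MUTATED if state.is_mutated else UNMUTATED if state.is_unmutated else np.nan
            )
        cols[f"{site.contig}:{site.pos}"] = col
    return pd.DataFrame(cols, index=list(calls.samples))


def pairwise_distance(m: pd.DataFrame) -> pd.DataFrame:
    """Shared-call distance: -1 per concordant site, +1 per discordant site.

    Only sites where both cells have a known call contribute; pairs with no
    shared site get NaN (unknown distance).
    """
    if len(m) < 2:
        raise ValueError("at least two cells required")
    cells = list(m.index)
    vals = m.to_numpy(dtype=object)
    known = ~pd.isna(m).to_numpy()
    n = len(cells)
    d = np.full((n, n), np.nan)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(i + 1, n):
            shared = known[i] & known[j]
            if not shared.any():
                continue
            same = (vals[i] == vals[j]) & shared
            d[i, j] = d[j, i] = int(shared.sum() - same.sum()) - int(same.sum())
    return pd.DataFrame(d, index=cells, columns=cells)


def cluster(distances: pd.DataFrame, k: int = 2):
    """Ward agglomerative clustering of the shared-call distances.

    Missing pairwise distances are imputed as 0 (neutral evidence) and the
    matrix is shifted to be non-negative before linkage — Ward requires
    proper distances while the shared-call score can be negative; the
    shift preserves rank order.  Returns (linkage, {cell: flat label}).
    """
    if len(distances) < 2:
        raise ValueError("at least two cells required")
    d = distances.to_numpy(dtype=float).copy()
    missing = np.isnan(d)
    if missing.any():
        log.warning("imputing %d missing pairwise distances as 0", int(missing.sum() // 2))
        d[missing] = 0.0
    np.fill_diagonal(d, 0.0)
    off = d[~np.eye(len(d), dtype=bool)]
    if off.size and off.min() < 0:
        d = d - off.min()
        np.fill_diagonal(d, 0.0)
    z = hierarchy.linkage(squareform(d, checks=False), method="ward")
    labels = hierarchy.fcluster(z, t=k, criterion="maxclust")
    return z, dict(zip(distances.index, (int(x) for x in labels)))


def dendrogram_newick(z: np.ndarray, leaf_names: list[str]) -> str:
    """Serialize a scipy linkage as a Newick tree with branch lengths."""
    tree = hierarchy.to_tree(z)

    def walk(node) -> str:
        if node.is_leaf():
            return leaf_names[node.id]
        left, right = node.left, node.right
        lb = node.dist - left.dist
        rb = node.dist - right.dist
        return f"({walk(left)}:{lb:g},{walk(right)}:{rb:g})"

    return walk(tree) + ";"


def implausibility_fdr(
    m: pd.DataFrame, clone_labels: Mapping[str, int]
) -> tuple[float | None, int, int]:
    """FDR estimate from biologically implausible genotype distributions.

    A site whose mutated calls are confined to one clone is plausible; a
    site mutated in two or more clones while at least one cell is
    unmutated is implausible (a true clonal variant cannot recur across
    unrelated clones); sites mutated in several clones with no unmutated
    cell are excluded — they may simply be germline variants.  Returns
    (implausible/(plausible+implausible), n_plausible, n_implausible).
    """
    clones = {clone_labels[c] for c in m.index}
    if len(clones) < 2:
        raise ValueError("implausibility FDR needs at least two clones")
    plausible = implausible = 0
    for col in m.columns:
        states = m[col]
        mut_clones = {clone_labels[c] for c in m.index if states[c] == MUTATED}
        n_unmut = int((states == UNMUTATED).sum())
        if not mut_clones:
            continue
        if len(mut_clones) == 1:
            plausible += 1
        elif n_unmut >= 1:
            implausible += 1
        # mutated in several clones, no unmutated cell: excluded (possible gSNV)
    total = plausible + implausible
    fdr = None if total == 0 else implausible / total
    return fdr, plausible, implausible


def plot_metric_grid(df: pd.DataFrame, value: str, path: str) -> None:
    """Heatmap of a metric over the (p_EAL, p_DO) grid; df needs columns
    p_eal, p_do and ``value``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pivot = df.pivot(index="p_eal", columns="p_do", values=value)
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(pivot.to_numpy(), origin="lower", vmin=0, vmax=1, cmap="viridis")
    ax.set_xticks(range(len(pivot.columns)), [f"{x:g}" for x in pivot.columns])
    ax.set_yticks(range(len(pivot.index)), [f"{y:g}" for y in pivot.index])
    ax.set_xlabel("p_DO")
    ax.set_ylabel("p_EAL")
    ax.set_title(value)
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
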