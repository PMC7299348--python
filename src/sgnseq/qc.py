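"""Marker-based sample purity checks and sample-correlation diagnostics.

The purity gate mirrors the study's wet-lab criterion applied in silico:
a cell-type marker must be at least 30-fold enriched in its home
population (e.g. the neuronal gene Mafb in SGNs vs glia) or at least
30-fold depleted when it marks a contaminating population (e.g. the hair
cell gene Myo6, the glial gene Sox10). Post-sequencing, all-vs-all
Pearson correlation of log expression shows replicates clustering by
group and SGNs separating from both references.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform


@dataclass(frozen=True)
class MarkerPanel:
    """One marker gene and where it is expected (or expected absent)."""

    gene_id: str
    expected_in: str
    expected_absent: tuple[str, ...]
    role: str = "other"  # neuronal / hair_cell / glial / housekeeping / other

    def __post_init__(self) -> None:
        if self.expected_in in self.expected_absent:
            raise ValueError(
                f"marker {self.gene_id!r}: expected_in group listed as absent"
            )


def default_marker_panels() -> list[MarkerPanel]:
    """The study's marker panel; gene ids are plain strings, replaceable."""
    sgn = "SGN_P8"
    panels = []
    for g in ("Mafb", "Slc17a6", "Slc17a7", "Lypd1"):
        panels.append(MarkerPanel(g, sgn, ("HC", "Glia"), "neuronal"))
    for g in ("Myo6", "Myo7a", "Pou4f3", "Gfi1"):
        panels.append(MarkerPanel(g, "HC", (sgn,), "hair_cell"))
    for g in ("Sox10", "Foxd3", "Plp1"):
        panels.append(MarkerPanel(g, "Glia", (sgn,), "glial"))
    for g in ("Gapdh", "Actg1", "Actb"):
        panels.append(MarkerPanel(g, sgn, (), "housekeeping"))
    return panels


def marker_fold(
    expr_group_means: pd.DataFrame,
    marker: str,
    target: str,
    reference: str,
    pseudo: float = 0.01,
) -> float:
    """(mean_target + pseudo) / (mean_reference + pseudo) for one marker."""
    if marker not in expr_group_means.index:
        raise KeyError(f"marker gene {marker!r} absent from expression matrix")
    num = float(expr_group_means.at[marker, target]) + pseudo
    den = float(expr_group_means.at[marker, reference]) + pseudo
    return num / den


def qc_gate(
    folds: dict[str, float],
    enrichment_markers: list[str],
    depletion_markers: list[str],
    fold_threshold: float = 30.0,
) -> tuple[bool, list[str]]:
    """30-fold enrichment/depletion gate; reasons name every failing marker.

    ``folds`` holds target-over-reference folds; enrichment markers must
    reach ``fold_threshold``-fold up, depletion markers must fall to at
    most ``1/fold_threshold``.
    """
    reasons = []
    for g in enrichment_markers:
        if folds[g] < fold_threshold:
            reasons.append(
                f"{g}: enrichment {folds[g]:.2f}-fold < required {fold_threshold:g}"
            )
    for g in depletion_markers:
        if folds[g] > 1.0 / fold_threshold:
            reasons.append(
                f"{g}: depletion {1.0 / folds[g]:.2f}-fold < required {fold_threshold:g}"
            )
    return (not reasons), reasons


def sample_correlation(logexpr: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """All-vs-all Pearson correlation of samples with a display ordering.

    Returns the symmetric correlation matrix on log expression plus the
    average-linkage hierarchical-clustering leaf order.
    """
    if logexpr.shape[1] < 2:
        raise ValueError("sample correlation needs at least 2 samples")
    sd = logexpr.std(axis=0)
    if (sd == 0).any():
        bad = sd.index[sd == 0].tolist()
        raise ValueError(f"zero-variance sample(s): {bad}")
    corr = logexpr.corr(method="pearson")
    dist = squareform(np.clip(1.0 - corr.to_numpy(), 0.0, None), checks=False)
    order = leaves_list(average(dist))
    return corr, [corr.columns[i] for i in order]


def qc_report(
    expr_group_means: pd.DataFrame,
    panels: list[MarkerPanel],
    sgn_group: str,
    fold_threshold: float = 30.0,
    pseudo: float = 0.01,
) -> pd.DataFrame:
    """Fold change and pass flag per marker against its off-target groups.

    Neuronal markers are tested as enriched in the SGN group relative to
    each expected-absent group; hair-cell and glial markers as depleted
    in SGNs relative to their home group; housekeeping markers only need
    detection everywhere, so they carry no fold requirement.
    """
    rows = []
    for p in panels:
        if p.role == "housekeeping":
            detected = bool((expr_group_means.loc[p.gene_id] > 0).all())
            rows.append((p.gene_id, p.role, "all", np.nan, detected))
            continue
        if p.role in ("hair_cell", "glial"):
            # contamination markers: SGN expression over home population
            fold = marker_fold(expr_group_means, p.gene_id, sgn_group, p.expected_in, pseudo)
            ok = fold <= 1.0 / fold_threshold
            rows.append((p.gene_id, p.role, p.expected_in, fold, ok))
        else:
            for absent in p.expected_absent:
                fold = marker_fold(expr_group_means, p.gene_id, p.expected_in, absent, pseudo)
                ok = fold >= fold_threshold
                rows.append((p.gene_id, p.role, absent, fold, ok))
    return pd.DataFrame(
        rows, columns=["marker", "role", "versus", "fold", "passed"]
    )
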