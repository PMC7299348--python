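"""Expression gates, SGN-specificity filters and the transition taxonomy.

Two filters define SGN-specific genes against the hair-cell and glia
references: the *constant* filter keeps genes enriched over both
references at every age while statistically flat across ages; the
*dynamic* filter keeps genes enriched at one or more ages that also change
significantly between ages. Independently, every gene expressed in SGNs
is assigned one symbol per consecutive-age transition — u (up), d (down),
- (unchanged) or n (noisy) — and the four symbols concatenate into a
pattern string such as ``u---`` or ``-d--``; for category grouping the
noisy symbol is merged into '-'.

All thresholds live in :class:`Thresholds`, whose defaults are the
published filter values.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .design import StudyDesign, HC_GROUP, GLIA_GROUP
from .io import CountMatrix
from .normalization import compute_cpm
from .diffexp import contrast_name

CONSTANT_SPECIFIC = "CONSTANT_SPECIFIC"
DYNAMIC_SPECIFIC = "DYNAMIC_SPECIFIC"
NONE_CALL = "NONE"


@dataclass
class Thresholds:
    """All filter and gate thresholds, in published units.

    Fold-change thresholds are linear (FC > 4 means |log2FC| > 2 for
    two-sided rules, signed for the specificity direction); q thresholds
    are BH-adjusted p-values; TPM thresholds apply to group means.
    """

    cpm_expr_gate: float = 1.0      # CPM > 1 in all replicates of >=1 group
    cpm_dyn_gate: float = 10.0      # CPM > 10 in all replicates of >=1 SGN age
    fc_specific: float = 4.0        # SGN-vs-reference enrichment
    q_specific: float = 0.01
    fc_sgn_flat: float = 2.0        # constant filter: all SGN pairs below this
    tpm_ref_max: float = 5.0        # reference means must stay below
    tpm_sgn_min_mean: float = 30.0  # constant filter: every age mean above
    q_dyn: float = 0.05             # dynamic filter: SGN-pair significance
    fc_dyn: float = 2.0
    tpm_dyn_max: float = 75.0       # dynamic filter: max age mean above
    ratio_dyn: float = 25.0         # max age mean vs each reference mean
    q_trans: float = 0.05           # transition up/down call
    fc_trans: float = 2.0
    q_unch: float = 0.1             # transition unchanged call
    fc_unch: float = 2.0
    fc_elem_max: float = 4.0        # max index-paired replicate fold change
    min_category_size: int = 10     # categories smaller than this unlisted
    qc_fold: float = 30.0           # marker enrichment/depletion gate
    elementwise_mode: str = "paired"  # or "all_pairs"

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name == "elementwise_mode":
                if v not in ("paired", "all_pairs"):
                    raise ValueError("elementwise_mode must be 'paired' or 'all_pairs'")
                continue
            if v <= 0:
                raise ValueError(f"threshold {f.name} must be positive")
            if f.name.startswith("fc_") and v < 1:
                raise ValueError(f"fold-change threshold {f.name} must be >= 1")
            if f.name.startswith("q_") and not (0 < v < 1):
                raise ValueError(f"q threshold {f.name} must be in (0, 1)")


def expression_gate(
    m: CountMatrix,
    th: Thresholds,
    mode: str = "de_universe",
    include_refs: bool = True,
) -> list[str]:
    """Genes passing the CPM expression gate, on raw library sizes.

    ``de_universe``: CPM above ``cpm_expr_gate`` in every replicate of at
    least one group (references included unless ``include_refs=False``).
    ``dynamics_universe``: same rule with ``cpm_dyn_gate`` over SGN ages
    only.
    """
    lib = m.lib_sizes.astype(float)
    if (lib == 0).any():
        # all-zero samples pass no gate; avoid a spurious division error
        lib = lib.where(lib > 0, 1.0)
    cpm = compute_cpm(m, lib)
    design = m.design
    if mode == "de_universe":
        groups = list(design.groups) if include_refs else list(design.sgn_age_order)
        cut = th.cpm_expr_gate
    elif mode == "dynamics_universe":
        groups = list(design.sgn_age_order)
        cut = th.cpm_dyn_gate
    else:
        raise ValueError(f"unknown gate mode {mode!r}")
    keep = np.zeros(cpm.shape[0], dtype=bool)
    for grp in groups:
        members = design.samples_in(grp)
        keep |= (cpm[members] > cut).all(axis=1).to_numpy()
    return [g for g, k in zip(cpm.index, keep) if k]


class ContrastIndex:
    """Fast (group_a, group_b) -> per-gene (log2FC, q) lookup with sign flips."""

    def __init__(self, contrasts: pd.DataFrame) -> None:
        self._tables: dict[tuple[str, str], pd.DataFrame] = {}
        for (a, b), sub in contrasts.groupby(["group_a", "group_b"], sort=False):
            self._tables[(a, b)] = sub.set_index("gene_id")[["log2FC", "q"]]
        first = next(iter(self._tables.values()))
        self.gene_ids = first.index

    def get(self, a: str, b: str) -> tuple[np.ndarray, np.ndarray]:
        """(log2FC of a over b, q) aligned to ``gene_ids``."""
        if (a, b) in self._tables:
            t = self._tables[(a, b)]
            return t["log2FC"].to_numpy(), t["q"].to_numpy()
        if (b, a) in self._tables:
            t = self._tables[(b, a)]
            return -t["log2FC"].to_numpy(), t["q"].to_numpy()
        raise KeyError(f"missing contrast for pair {contrast_name(a, b)}")


def specificity_calls(
    contrasts: pd.DataFrame,
    tpm_group_means: pd.DataFrame,
    th: Thresholds,
    design: StudyDesign,
) -> pd.DataFrame:
    """Constant/dynamic SGN-specificity calls with per-condition audit booleans.

    Returns one row per gene in the contrast table with columns ``call``
    and the eight audit booleans ``const_c1..c4`` / ``dyn_c1..c4``.
    """
    if not design.has_references:
        raise ValueError("specificity filters need HC and Glia reference groups")
    idx = ContrastIndex(contrasts)
    genes = idx.gene_ids
    ages = list(design.sgn_age_order)
    tpm = tpm_group_means.reindex(genes)

    lfc_vs_ref = {}  # (age, ref) -> log2FC, q
    for age in ages:
        for ref in (HC_GROUP, GLIA_GROUP):
            lfc_vs_ref[(age, ref)] = idx.get(age, ref)
    age_pairs = [(a, b) for i, a in enumerate(ages) for b in ages[i + 1:]]
    lfc_pairs = {pair: idx.get(*pair) for pair in age_pairs}

    log_fc_spec = np.log2(th.fc_specific)
    log_fc_flat = np.log2(th.fc_sgn_flat)
    log_fc_dyn = np.log2(th.fc_dyn)

    # constant condition 1: every age enriched over both references
    c1 = np.ones(len(genes), dtype=bool)
    # dynamic condition 1: some age enriched over both references
    d1 = np.zeros(len(genes), dtype=bool)
    for age in ages:
        per_age = np.ones(len(genes), dtype=bool)
        for ref in (HC_GROUP, GLIA_GROUP):
            lfc, q = lfc_vs_ref[(age, ref)]
            per_age &= (q < th.q_specific) & (lfc > log_fc_spec)
        c1 &= per_age
        d1 |= per_age

    # constant condition 2: flat across all age pairs (no q requirement)
    c2 = np.ones(len(genes), dtype=bool)
    # dynamic condition 2: at least one significantly changed age pair
    d2 = np.zeros(len(genes), dtype=bool)
    for pair in age_pairs:
        lfc, q = lfc_pairs[pair]
        c2 &= np.abs(lfc) < log_fc_flat
        d2 |= (q < th.q_dyn) & (np.abs(lfc) > log_fc_dyn)

    ref_means = tpm[[HC_GROUP, GLIA_GROUP]].to_numpy()
    age_means = tpm[ages].to_numpy()
    c3 = (ref_means < th.tpm_ref_max).all(axis=1)
    c4 = (age_means > th.tpm_sgn_min_mean).all(axis=1)
    max_age = age_means.max(axis=1)
    d3 = max_age > th.tpm_dyn_max
    d4 = (max_age[:, None] >= th.ratio_dyn * ref_means).all(axis=1)

    const = c1 & c2 & c3 & c4
    dyn = d1 & d2 & d3 & d4
    call = np.where(const, CONSTANT_SPECIFIC, np.where(dyn, DYNAMIC_SPECIFIC, NONE_CALL))
    return pd.DataFrame(
        {
            "gene_id": genes,
            "call": call,
            "const_c1": c1, "const_c2": c2, "const_c3": c3, "const_c4": c4,
            "dyn_c1": d1, "dyn_c2": d2, "dyn_c3": d3, "dyn_c4": d4,
        }
    ).set_index("gene_id")


def constant_specific_filter(
    contrasts: pd.DataFrame,
    tpm_group_means: pd.DataFrame,
    th: Thresholds,
    design: StudyDesign,
) -> set[str]:
    """Gene ids passing all four constant-specificity conditions."""
    calls = specificity_calls(contrasts, tpm_group_means, th, design)
    return set(calls.index[calls["call"] == CONSTANT_SPECIFIC])


def dynamic_specific_filter(
    contrasts: pd.DataFrame,
    tpm_group_means: pd.DataFrame,
    th: Thresholds,
    design: StudyDesign,
) -> set[str]:
    """Gene ids passing all four dynamic-specificity conditions."""
    calls = specificity_calls(contrasts, tpm_group_means, th, design)
    return set(calls.index[calls["call"] == DYNAMIC_SPECIFIC])


def _max_elementwise_fc(
    cpm_a: np.ndarray, cpm_b: np.ndarray, mode: str = "paired"
) -> np.ndarray:
    """Largest two-sided replicate-level fold change, pseudo-count 1 CPM.

    ``paired`` divides replicate i of the later age by replicate i of the
    earlier age; ``all_pairs`` considers every replicate pair.
    """
    a = cpm_a + 1.0
    b = cpm_b + 1.0
    if mode == "paired":
        k = min(a.shape[1], b.shape[1])
        ratio = b[:, :k] / a[:, :k]
    elif mode == "all_pairs":
        ratio = (b[:, None, :] / a[:, :, None]).reshape(a.shape[0], -1)
    else:
        raise ValueError(f"unknown elementwise mode {mode!r}")
    return np.maximum(ratio, 1.0 / ratio).max(axis=1)


def call_transitions(
    contrasts: pd.DataFrame,
    cpm: pd.DataFrame,
    th: Thresholds,
    design: StudyDesign,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """One u/d/-/n symbol per gene per consecutive-age transition.

    ``cpm`` should be TMM-normalized CPM (used only by the element-wise
    fold-change clause of the unchanged rule). log2FC is oriented later
    age over earlier age, so u means expression rises with age.
    """
    idx = ContrastIndex(contrasts)
    genes = list(genes) if genes is not None else list(idx.gene_ids)
    pos = pd.Index(idx.gene_ids).get_indexer(genes)
    if (pos < 0).any():
        missing = [g for g, p in zip(genes, pos) if p < 0]
        raise KeyError(f"genes absent from contrasts: {missing[:5]}")
    ages = list(design.sgn_age_order)
    out = {}
    log_fc_trans = np.log2(th.fc_trans)
    log_fc_unch = np.log2(th.fc_unch)
    for earlier, later in zip(ages[:-1], ages[1:]):
        lfc, q = idx.get(later, earlier)
        lfc, q = lfc[pos], q[pos]
        cpm_a = cpm.loc[genes, design.samples_in(earlier)].to_numpy()
        cpm_b = cpm.loc[genes, design.samples_in(later)].to_numpy()
        elem = _max_elementwise_fc(cpm_a, cpm_b, th.elementwise_mode)
        up = (q < th.q_trans) & (lfc > log_fc_trans)
        down = (q < th.q_trans) & (lfc < -log_fc_trans)
        unchanged = (
            (q > th.q_unch)
            & (np.abs(lfc) < log_fc_unch)
            & (elem < th.fc_elem_max)
        )
        sym = np.full(len(genes), "n")
        sym[unchanged] = "-"
        sym[up] = "u"
        sym[down] = "d"
        out[f"{earlier}->{later}"] = sym
    return pd.DataFrame(out, index=pd.Index(genes, name="gene_id"))


def pattern_string(calls) -> tuple[str, str]:
    """(raw, category) pattern labels from 4 transition symbols.

    The raw label keeps 'n'; the category label merges noisy into '-'.
    """
    calls = list(calls)
    if len(calls) != 4:
        raise ValueError(f"expected exactly 4 transition calls, got {len(calls)}")
    for c in calls:
        if c not in ("u", "d", "-", "n"):
            raise ValueError(f"invalid transition symbol {c!r}")
    raw = "".join(calls)
    category = raw.replace("n", "-")
    return raw, category


def assign_patterns(transitions: pd.DataFrame) -> pd.DataFrame:
    """Per-gene raw and category pattern strings from the transition table."""
    raws, cats = [], []
    for row in transitions.itertuples(index=False):
        raw, cat = pattern_string(row)
        raws.append(raw)
        cats.append(cat)
    return pd.DataFrame(
        {"raw": raws, "category": cats}, index=transitions.index
    )


def group_patterns(
    patterns: pd.DataFrame, th: Thresholds
) -> tuple[dict[str, list[str]], pd.DataFrame]:
    """Partition genes by category label.

    Returns the full category -> gene-id mapping plus a summary table
    flagging which categories are large enough (> ``min_category_size``)
    to be reported; the complete listing is always retained.
    """
    mapping: dict[str, list[str]] = {}
    for gid, cat in patterns["category"].items():
        mapping.setdefault(cat, []).append(gid)
    summary = pd.DataFrame(
        {
            "category": list(mapping),
            "n_genes": [len(v) for v in mapping.values()],
        }
    ).sort_values("n_genes", ascending=False, ignore_index=True)
    summary["shown_in_report"] = summary["n_genes"] > th.min_category_size
    return mapping, summary


# ---------------------------------------------------------------------------
# noise-free oracle: the filters applied to true group means, with
# "significant" meaning the fold-change condition holds on the true means
# ---------------------------------------------------------------------------

def specificity_on_true_means(
    tpm_means: pd.DataFrame, th: Thresholds, design: StudyDesign
) -> pd.Series:
    """Specificity calls from noise-free group means.

    Statistical significance is replaced by the corresponding fold-change
    condition on true means, which is what a test would detect with
    unbounded replication.
    """
    ages = list(design.sgn_age_order)
    age_means = tpm_means[ages].to_numpy(dtype=float)
    ref_means = tpm_means[[HC_GROUP, GLIA_GROUP]].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc_vs_ref = age_means[:, :, None] / ref_means[:, None, :]
        fc_vs_ref = np.nan_to_num(fc_vs_ref, nan=1.0, posinf=np.inf)
        ratio = age_means[:, :, None] / age_means[:, None, :]
        ratio = np.nan_to_num(ratio, nan=1.0, posinf=np.inf)
        inv = np.where(ratio > 0, 1.0 / ratio, np.inf)
    pair_fc = np.maximum(ratio, inv)
    iu = np.triu_indices(len(ages), k=1)
    pair_fc = pair_fc[:, iu[0], iu[1]]

    c1 = (fc_vs_ref > th.fc_specific).all(axis=(1, 2))
    c2 = (pair_fc < th.fc_sgn_flat).all(axis=1)
    c3 = (ref_means < th.tpm_ref_max).all(axis=1)
    c4 = (age_means > th.tpm_sgn_min_mean).all(axis=1)
    d1 = (fc_vs_ref > th.fc_specific).all(axis=2).any(axis=1)
    d2 = (pair_fc > th.fc_dyn).any(axis=1)
    max_age = age_means.max(axis=1)
    d3 = max_age > th.tpm_dyn_max
    d4 = (max_age[:, None] >= th.ratio_dyn * ref_means).all(axis=1)
    call = np.where(
        c1 & c2 & c3 & c4,
        CONSTANT_SPECIFIC,
        np.where(d1 & d2 & d3 & d4, DYNAMIC_SPECIFIC, NONE_CALL),
    )
    return pd.Series(call, index=tpm_means.index)


def transitions_on_true_means(
    tpm_means: pd.DataFrame, th: Thresholds, design: StudyDesign
) -> pd.Series:
    """Category pattern implied by true means (fold-change rule only)."""
    ages = list(design.sgn_age_order)
    cats = []
    for gid, row in tpm_means.iterrows():
        syms = []
        for earlier, later in zip(ages[:-1], ages[1:]):
            a, b = float(row[earlier]), float(row[later])
            fc = (b + 1e-12) / (a + 1e-12)
            if fc > th.fc_trans:
                syms.append("u")
            elif fc < 1.0 / th.fc_trans:
                syms.append("d")
            else:
                syms.append("-")
        cats.append("".join(syms))
    return pd.Series(cats, index=tpm_means.index)
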