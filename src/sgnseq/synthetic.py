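"""Synthetic count matrices with planted ground truth.

The generator emulates the study's layout — five SGN ages with replicate
libraries plus pooled HC and glia references — and plants gene classes
whose true means satisfy, by construction, the downstream filters'
conditions: constant SGN-specific, dynamic SGN-specific, HC-specific,
glia-specific, housekeeping, transition-patterned, high-dispersion noisy,
and flat background genes. Counts are negative-binomial around
length-weighted library allocations of the true TPM-scale means, with a
decreasing mean-dispersion trend so the log-CPM mean-variance relation is
non-trivial. A truth table mapping every gene to its class and intended
pattern is emitted beside the counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import StudyDesign, SGN_AGE_ORDER, HC_GROUP, GLIA_GROUP, generate_design
from .io import CountMatrix

GENE_CLASSES = (
    "constant_specific",
    "dynamic_specific",
    "hc_specific",
    "glia_specific",
    "housekeeping",
    "patterned",
    "noisy",
    "background",
)

DEFAULT_PATTERNS = ("u---", "-d--", "ud--", "--u-", "---d", "uu--")

# dispersion trend: phi = DISP_A / mean_count + DISP_B
# DISP_B = BCV^2 with BCV 0.2, typical of well-controlled inbred-mouse bulk
DISP_A = 3.0
DISP_B = 0.04


@dataclass
class PlantedGeneSpec:
    """True per-group means (TPM scale), dispersion and length of one gene."""

    gene_id: str
    class_label: str
    means: dict[str, float]          # group -> true mean, TPM scale
    dispersion: float | None = None  # None: follow the mean-dispersion trend
    length: float = 1000.0
    intended_pattern: str | None = None

    def __post_init__(self) -> None:
        if self.class_label not in GENE_CLASSES:
            raise ValueError(f"unknown gene class {self.class_label!r}")
        if any(v < 0 for v in self.means.values()):
            raise ValueError(f"gene {self.gene_id}: negative true mean")
        if self.dispersion is not None and self.dispersion < 0:
            raise ValueError(f"gene {self.gene_id}: negative dispersion")
        if self.length <= 0:
            raise ValueError(f"gene {self.gene_id}: non-positive length")


def _logu(rng: np.random.Generator, lo: float, hi: float, size=None):
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size))


def default_panel(
    rng_or_seed: np.random.Generator | int,
    n_background: int = 2000,
    n_per_class: int = 50,
    patterns: tuple[str, ...] = DEFAULT_PATTERNS,
) -> list[PlantedGeneSpec]:
    """The default planted gene panel.

    2000 flat background genes plus ``n_per_class`` genes for each planted
    class; transition-patterned genes get ``n_per_class`` genes per
    intended pattern. Lengths are log-uniform in 500-10000 bases.
    SGN-vs-reference effects span roughly 4-100x on top of reference
    levels chosen to respect the TPM gates with margin.
    """
    rng = (
        rng_or_seed
        if isinstance(rng_or_seed, np.random.Generator)
        else np.random.default_rng(rng_or_seed)
    )
    ages = list(SGN_AGE_ORDER)
    all_groups = ages + [HC_GROUP, GLIA_GROUP]
    specs: list[PlantedGeneSpec] = []

    def flat(level: float) -> dict[str, float]:
        return {g: level for g in all_groups}

    def add(gid, label, means, dispersion=None, pattern=None):
        specs.append(
            PlantedGeneSpec(
                gid, label, means,
                dispersion=dispersion,
                length=float(_logu(rng, 500, 10_000)),
                intended_pattern=pattern,
            )
        )

    for i in range(n_background):
        add(f"bg_{i:04d}", "background", flat(float(_logu(rng, 0.3, 300))))

    for i in range(n_per_class):
        add(f"hk_{i:03d}", "housekeeping", flat(float(_logu(rng, 50, 400))))

    # planted specific/patterned genes get lengths >= 1500-2000 b so their
    # count depth supports the gates and fold thresholds they must satisfy
    for i in range(n_per_class):
        m = float(_logu(rng, 120, 250))
        # 50-100x over references, with references kept below 2.5 TPM so
        # the <5 TPM condition holds with margin under counting noise
        eff = float(_logu(rng, max(50.0, m / 2.5), 100))
        means = {g: m for g in ages}
        means[HC_GROUP] = m / eff
        means[GLIA_GROUP] = m / eff * float(_logu(rng, 0.5, 2.0))
        specs.append(
            PlantedGeneSpec(
                f"const_{i:03d}", "constant_specific", means,
                length=float(_logu(rng, 4000, 10_000)),
            )
        )

    for i in range(n_per_class):
        peak = float(_logu(rng, 150, 400))
        trough = peak / float(_logu(rng, 3, 10))
        # 60-100x below the peak age; the second reference may sit up to
        # 2x higher, keeping both at least 30x below the peak (>25x rule)
        ref = peak / float(_logu(rng, 60, 100))
        shape = rng.choice(["rise", "fall", "peak"])
        if shape == "rise":
            traj = np.geomspace(trough, peak, len(ages))
        elif shape == "fall":
            traj = np.geomspace(peak, trough, len(ages))
        else:
            half = (len(ages) + 1) // 2
            up = np.geomspace(trough, peak, half)
            traj = np.concatenate([up, np.geomspace(peak, trough, len(ages) - half + 1)[1:]])
        means = {g: float(t) for g, t in zip(ages, traj)}
        means[HC_GROUP] = ref
        means[GLIA_GROUP] = ref * float(_logu(rng, 0.5, 2.0))
        specs.append(
            PlantedGeneSpec(
                f"dyn_{i:03d}", "dynamic_specific", means,
                length=float(_logu(rng, 4000, 10_000)),
            )
        )

    for i in range(n_per_class):
        home = float(_logu(rng, 50, 400))
        means = flat(home / float(_logu(rng, 25, 100)))
        means[HC_GROUP] = home
        add(f"hc_{i:03d}", "hc_specific", means)

    for i in range(n_per_class):
        home = float(_logu(rng, 50, 400))
        means = flat(home / float(_logu(rng, 25, 100)))
        means[GLIA_GROUP] = home
        add(f"glia_{i:03d}", "glia_specific", means)

    for pat in patterns:
        for i in range(n_per_class):
            level = float(_logu(rng, 120, 250))
            step = float(_logu(rng, 5, 8))  # safely above the 2x call threshold
            traj = [1.0]
            for sym in pat:
                if sym == "u":
                    traj.append(traj[-1] * step)
                elif sym == "d":
                    traj.append(traj[-1] / step)
                else:
                    traj.append(traj[-1])
            traj = np.asarray(traj)
            # anchor at the geometric mean so up- and down-patterns carry
            # comparable TPM mass at every age (keeps composition stable)
            traj = traj / np.exp(np.mean(np.log(traj))) * level
            means = {g: float(t) for g, t in zip(ages, traj)}
            base = float(np.exp(np.mean(np.log(traj))))
            means[HC_GROUP] = base  # shared with references: not SGN-specific
            means[GLIA_GROUP] = base
            specs.append(
                PlantedGeneSpec(
                    f"pat{pat.replace('-', '_')}_{i:03d}", "patterned", means,
                    length=float(_logu(rng, 1500, 10_000)),
                    intended_pattern=pat,
                )
            )

    for i in range(n_per_class):
        add(f"noisy_{i:03d}", "noisy", flat(float(_logu(rng, 20, 100))), dispersion=2.0)

    return _normalize_to_tpm(specs, all_groups)


def _normalize_to_tpm(
    specs: list[PlantedGeneSpec], groups: list[str]
) -> list[PlantedGeneSpec]:
    """Scale background genes so group true-mean sums average 1e6.

    True means are on the TPM scale only if each group's composition sums
    to a million. Planted classes keep their exact levels (their
    filter-defining ratios and thresholds must not move) and the flat
    background is scaled by one global factor, so flat genes stay flat
    and remain the compositional majority. Planted mass is balanced
    across ages by construction, so per-group sums land within a few
    percent of 1e6.
    """
    bg = [s for s in specs if s.class_label == "background"]
    if not bg:
        return specs
    planted_sums = [
        sum(s.means.get(g, 0.0) for s in specs if s.class_label != "background")
        for g in groups
    ]
    bg_sum = sum(s.means.get(groups[0], 0.0) for s in bg)
    target = 1e6 - float(np.mean(planted_sums))
    if target <= 0 or bg_sum <= 0:
        raise ValueError("planted classes exceed the TPM budget; add background mass")
    scale = target / bg_sum
    for s in bg:
        for g in list(s.means):
            s.means[g] *= scale
    return specs


def generate_counts(
    design: StudyDesign,
    specs: list[PlantedGeneSpec],
    lib_size_range: tuple[float, float] = (0.8e6, 1.2e6),
    seed: int = 0,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Draw negative-binomial counts for every sample of the design.

    Each sample's target library size is uniform in ``lib_size_range``;
    a gene's expected count is its length-weighted share of the group's
    true TPM composition times that target. Dispersion follows
    ``DISP_A/mean + DISP_B`` unless the gene's spec pins it. Identical inputs
    and seed give bit-identical output. Returns the count matrix and the
    truth table (class, intended pattern, true means per group).
    """
    if not specs:
        raise ValueError("specs must be non-empty")
    rng = np.random.default_rng(seed)
    gene_ids = [s.gene_id for s in specs]
    if len(set(gene_ids)) != len(gene_ids):
        raise ValueError("duplicate gene ids in specs")
    lengths = np.array([s.length for s in specs])
    groups = list(design.groups)
    tpm = np.array([[s.means.get(g, 0.0) for g in groups] for s in specs])

    # length-weighted allocation: counts are proportional to tpm * length
    alloc = tpm * lengths[:, None]
    colsum = alloc.sum(axis=0)
    colsum[colsum == 0] = 1.0
    frac = alloc / colsum

    lo, hi = lib_size_range
    if not (0 < lo <= hi):
        raise ValueError("invalid lib_size_range")
    sample_ids = design.sample_ids
    lib_targets = rng.uniform(lo, hi, size=len(sample_ids))

    counts = np.zeros((len(specs), len(sample_ids)), dtype=np.int64)
    grand_mu = (frac * 1e6).mean(axis=1)  # nominal per-gene mean count
    phi = np.where(grand_mu > 0, DISP_A / np.maximum(grand_mu, 1e-8) + DISP_B, DISP_B)
    pinned = np.array([s.dispersion if s.dispersion is not None else np.nan for s in specs])
    phi = np.where(np.isnan(pinned), phi, pinned)

    group_col = {g: i for i, g in enumerate(groups)}
    for j, sid in enumerate(sample_ids):
        g = design.group_of[sid]
        mu = frac[:, group_col[g]] * lib_targets[j]
        pois = phi <= 1e-12
        counts[pois, j] = rng.poisson(mu[pois])
        nb = ~pois
        if nb.any():
            r = 1.0 / phi[nb]
            p = r / (r + mu[nb])
            counts[nb, j] = rng.negative_binomial(r, p)

    cdf = pd.DataFrame(counts, index=gene_ids, columns=sample_ids)
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "class_label": [s.class_label for s in specs],
            "intended_pattern": [s.intended_pattern or "" for s in specs],
            "dispersion": phi,
            "length": lengths,
        }
    ).set_index("gene_id")
    for g in groups:
        truth[f"true_mean_{g}"] = [s.means.get(g, 0.0) for s in specs]
    matrix = CountMatrix(cdf, design, pd.Series(lengths, index=gene_ids))
    return matrix, truth


def true_means_frame(truth: pd.DataFrame, design: StudyDesign) -> pd.DataFrame:
    """Extract the genes x groups true-mean matrix from a truth table."""
    cols = {g: truth[f"true_mean_{g}"] for g in design.groups}
    return pd.DataFrame(cols, index=truth.index)


def generate_annotations(
    genes: list[str],
    n_groups: int,
    planted_group: str,
    planted_set: list[str],
    seed: int = 0,
) -> dict[str, set[str]]:
    """Random gene-group partition with one group enriched by construction.

    Every gene is assigned to one of ``n_groups`` groups uniformly at
    random, then all members of ``planted_set`` are moved into
    ``planted_group``, making that group maximally enriched in the
    planted query. GMT-writable via :func:`sgnseq.io.write_gmt`.
    """
    if n_groups < 1:
        raise ValueError("need at least one gene group")
    genes = list(genes)
    missing = set(planted_set) - set(genes)
    if missing:
        raise ValueError(f"planted_set genes outside universe: {sorted(missing)[:5]}")
    rng = np.random.default_rng(seed)
    names = [planted_group] + [f"group_{i:02d}" for i in range(1, n_groups)]
    assign = rng.integers(0, n_groups, size=len(genes))
    sets: dict[str, set[str]] = {name: set() for name in names}
    for g, a in zip(genes, assign):
        sets[names[a]].add(g)
    for g in planted_set:
        for s in sets.values():
            s.discard(g)
        sets[planted_group].add(g)
    return sets


def null_dataset(
    seed: int = 0,
    n_genes: int = 2000,
    n_reps_per_age: int = 3,
    lib_size_range: tuple[float, float] = (0.8e6, 1.2e6),
) -> CountMatrix:
    """SGN-only dataset with no group effects: every gene flat across ages.

    Used for type-I-error calibration of the moderated tests; expression
    levels and dispersions follow the default background distribution.
    """
    design = generate_design(n_reps_per_age, include_refs=False)
    rng = np.random.default_rng(seed)
    ages = list(SGN_AGE_ORDER)
    specs = [
        PlantedGeneSpec(
            f"null_{i:04d}",
            "background",
            {g: lvl for g in ages},
            length=float(_logu(rng, 500, 10_000)),
        )
        for i, lvl in enumerate(_logu(rng, 0.3, 300, n_genes))
    ]
    m, _ = generate_counts(design, specs, lib_size_range, seed=seed + 1)
    return m


def synthetic_dataset(
    seed: int = 0,
    n_reps_per_age: int = 3,
    include_refs: bool = True,
    n_reps_refs: int = 3,
    lib_size_range: tuple[float, float] = (0.8e6, 1.2e6),
    **panel_kwargs,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Default study-design dataset: design + panel + counts in one call.

    The reference populations default to 3 replicate libraries each: the
    expression gate counts "all replicates" within the HC and glia groups
    too, so the emulated study carries replicated references.
    """
    design = generate_design(n_reps_per_age, include_refs, n_reps_refs)
    specs = default_panel(np.random.default_rng(seed), **panel_kwargs)
    return generate_counts(design, specs, lib_size_range, seed=seed + 1)
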