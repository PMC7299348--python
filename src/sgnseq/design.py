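"""Study design: sample-to-group assignment for the SGN developmental series.

The study profiles spiral ganglion neurons (SGNs) at five ages — E15.5, P1,
P8, P14 and P30 — with replicate libraries per age, plus two reference
populations, hair cells (HC) and cochlear glia, against which SGN
specificity is defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

SGN_AGE_ORDER = ("SGN_E15.5", "SGN_P1", "SGN_P8", "SGN_P14", "SGN_P30")
HC_GROUP = "HC"
GLIA_GROUP = "Glia"
REFERENCE_GROUPS = (HC_GROUP, GLIA_GROUP)

#: the four consecutive-age transitions, in developmental order
TRANSITIONS = tuple(zip(SGN_AGE_ORDER[:-1], SGN_AGE_ORDER[1:]))


class DesignError(ValueError):
    """Raised when a study design violates its invariants."""


@dataclass(frozen=True)
class StudyDesign:
    """Ordered groups and the samples assigned to them.

    Parameters
    ----------
    groups
        Ordered group labels (SGN ages first, references last).
    samples
        ``(sample_id, group, replicate_index)`` triples.
    sgn_age_order
        The subset of ``groups`` that are SGN ages, in developmental order.
    """

    groups: tuple[str, ...]
    samples: tuple[tuple[str, str, int], ...]
    sgn_age_order: tuple[str, ...] = SGN_AGE_ORDER

    def __post_init__(self) -> None:
        seen = set()
        for sid, grp, _ in self.samples:
            if sid in seen:
                raise DesignError(f"duplicate sample id {sid!r}")
            seen.add(sid)
            if grp not in self.groups:
                raise DesignError(f"sample {sid!r} assigned to unknown group {grp!r}")
        for age in self.sgn_age_order:
            if age not in self.groups:
                raise DesignError(f"SGN age {age!r} missing from groups")

    @property
    def sample_ids(self) -> list[str]:
        return [s[0] for s in self.samples]

    @property
    def group_of(self) -> dict[str, str]:
        return {sid: grp for sid, grp, _ in self.samples}

    def samples_in(self, group: str) -> list[str]:
        if group not in self.groups:
            raise DesignError(f"unknown group {group!r}")
        return [sid for sid, grp, _ in self.samples if grp == group]

    @property
    def has_references(self) -> bool:
        return all(g in self.groups for g in REFERENCE_GROUPS)

    def validate_replicates(self, minimum: int = 2) -> None:
        """Require ``minimum`` replicates per group (residual df for modeling)."""
        for grp in self.groups:
            n = len(self.samples_in(grp))
            if n < minimum:
                raise DesignError(
                    f"group {grp!r} has {n} replicate(s); at least {minimum} required"
                )


def generate_design(
    n_reps_per_age: int,
    include_refs: bool = True,
    n_reps_refs: int = 1,
) -> StudyDesign:
    """Build the canonical study layout: five SGN ages, optional HC/Glia.

    With ``n_reps_per_age=3`` and references this reproduces the study's
    17-sample, 7-group layout: 5 ages x 3 replicates plus one pooled HC and
    one pooled glia library.
    """
    if n_reps_per_age < 2:
        raise DesignError("at least 2 replicates per SGN age are required")
    if n_reps_refs < 1:
        raise DesignError("reference groups need at least 1 sample")
    groups = list(SGN_AGE_ORDER)
    samples: list[tuple[str, str, int]] = []
    for age in SGN_AGE_ORDER:
        for r in range(1, n_reps_per_age + 1):
            samples.append((f"{age}_rep{r}", age, r))
    if include_refs:
        for ref in REFERENCE_GROUPS:
            groups.append(ref)
            if n_reps_refs == 1:
                samples.append((f"{ref}_pool", ref, 1))
            else:
                for r in range(1, n_reps_refs + 1):
                    samples.append((f"{ref}_rep{r}", ref, r))
    return StudyDesign(tuple(groups), tuple(samples))
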