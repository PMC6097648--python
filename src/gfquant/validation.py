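"""Phantom-study validation harness.

Canned synthetic experiments used to check that the full pipeline recovers
constructed group effects with the right sign and significance, and that it
stays quiet under the null.  The recovery study mirrors the four-genotype
design: a control, a group with a 4-fold JO-B gap-junction plaque load (the
ShakB(N+16)-like manipulation), a group with reduced dye coupling (the
ShakB(N)-like manipulation) and a group with more active zones plus longer
medial branches (the Engrailed-like positive control).  The construction
dissociates the effects: the plaque-only group must light up the ShakB
measures and nothing else.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import PhantomSpec, generate_group_study
from .pipeline import PipelineConfig, run_study

__all__ = ["RECOVERY_EFFECTS", "recovery_study", "null_study", "derive_seeds"]

#: Group -> effect multipliers of the standard recovery study.
RECOVERY_EFFECTS = {
    "con": {},
    "shb_plus": {"shb_jo_b": 4.0},
    "coupling_minus": {"nb_axons": 0.25},
    "en_like": {"az_count": 2.5, "medial_branch": 2.0},
}

STUDY_CHANNELS = ("GF", "NB", "Brp", "ShB")


def derive_seeds(seed: int, n: int) -> list[int]:
    """n reproducible child seeds (each < 2**31) from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s & 0x7FFFFFFF) for s in ss.generate_state(n)]


@dataclass
class RecoveryOutcome:
    seed: int
    shb_jo_b_fold: float
    shb_jo_b_p: float
    az_fold: float
    az_p: float
    medial_fold: float
    medial_p: float
    az_p_shb_group: float
    recovered: bool


def recovery_study(
    seed: int,
    n_per_group: int = 8,
    shape: tuple = (60, 128, 128),
    config: PipelineConfig | None = None,
) -> RecoveryOutcome:
    """Run one seeded 4-group recovery study through the full pipeline.

    Recovery means: the constructed JO-B plaque effect and the active-zone
    and medial-branch effects all come out with the correct sign and a Tukey
    p <= 0.05 against control, while the plaque-only group earns no star on
    the active-zone-on-dendrite measure.
    """
    config = config or PipelineConfig()
    base = PhantomSpec(shape=shape)
    study = generate_group_study(
        base, RECOVERY_EFFECTS, n_per_group=n_per_group, seed=seed, channels=STUDY_CHANNELS
    )
    results, reports = run_study(config, study)
    means = results.groupby("group").mean(numeric_only=True)

    def fold(measure, group):
        con = means.loc["con", measure]
        return float(means.loc[group, measure] / con) if con > 0 else float("inf")

    shb_fold = fold("shb_volume_jo_b", "shb_plus")
    shb_p = reports["shb_volume_jo_b"].pair_p("con", "shb_plus")
    az_fold = fold("az_on_gf_volume", "en_like")
    az_p = reports["az_on_gf_volume"].pair_p("con", "en_like")
    medial_fold = fold("medial_surface_area", "en_like")
    medial_p = reports["medial_surface_area"].pair_p("con", "en_like")
    az_p_shb = reports["az_on_gf_volume"].pair_p("con", "shb_plus")

    recovered = (
        shb_fold > 1.0 and shb_p <= 0.05
        and az_fold > 1.0 and az_p <= 0.05
        and medial_fold > 1.0 and medial_p <= 0.05
        and az_p_shb > 0.05
    )
    return RecoveryOutcome(
        seed, shb_fold, shb_p, az_fold, az_p, medial_fold, medial_p, az_p_shb, recovered
    )


@dataclass
class NullOutcome:
    seed: int
    n_measures: int
    n_starred: int


def null_study(
    seed: int,
    n_per_group: int = 8,
    n_groups: int = 4,
    shape: tuple = (60, 128, 128),
    config: PipelineConfig | None = None,
) -> NullOutcome:
    """One seeded study with exchangeable groups (all multipliers 1).

    A measure counts as starred when any Tukey pairwise comparison reaches
    p <= 0.05; under exchangeability that should stay near the family-wise
    5% level.
    """
    config = config or PipelineConfig()
    base = PhantomSpec(shape=shape)
    effects = {f"g{i}": {} for i in range(n_groups)}
    study = generate_group_study(
        base, effects, n_per_group=n_per_group, seed=seed, channels=STUDY_CHANNELS
    )
    _results, reports = run_study(config, study)
    n_starred = sum(1 for r in reports.values() if r.any_star())
    return NullOutcome(seed, len(reports), n_starred)
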