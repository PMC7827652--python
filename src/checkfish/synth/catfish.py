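"""Two-epoch IEG nucleus-population simulator.

Each simulated nucleus carries a latent pair ``(active_e1, active_e2)``:
whether the neuron was transcriptionally activated in the first (A1,
reported by the green Homer1a channel) and second (A2, reported by the
orange/red Arc channel) exploration session.  The pair is drawn from a
2x2 joint law parameterised by the two marginal activity probabilities
and a target ensemble-overlap similarity

    p_double = p1*p2 + s * (min(p1, p2) - p1*p2),

which is inverted to the four cell probabilities and rejected loudly if
any cell would be negative.  Channel focus intensities are drawn from a
positive or negative distribution according to the latent state, so the
downstream threshold classifier has a recoverable ground truth.

The simulated study design is the 2x2 day-11 layout: treatment (QNP /
control) crossed with environment (arena-exploring A1A2 / home-cage HC),
with home-cage animals at a low activity baseline.  A fraction of records
mimics glial nuclei (small, elongated, bright counterstain, no IEG
signal), and the weakest true-positive nuclei per slide x region x
channel among exploring animals are flagged as threshold exemplars,
mirroring the manual picks used to calibrate the classifier; home-cage
animals are never flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Sequence, Tuple, Union

import numpy as np
import pandas as pd

__all__ = ["CatfishSimConfig", "joint_activity_law", "simulate_catfish_population"]

REGIONS = ("CA1", "ACC", "OFC", "mPFC")
TREATMENTS = ("QNP", "control")
ENVIRONMENTS = ("A1A2", "HC")


class SimConfigurationError(ValueError):
    """Raised when a configuration implies an invalid joint activity law."""


def joint_activity_law(p1: float, p2: float, similarity: float) -> Dict[str, float]:
    """Invert (p1, p2, similarity) to the four-cell joint activity law.

    Returns the probabilities of (negative, e1-only, e2-only, double).
    Raises :class:`SimConfigurationError` when the implied law has a
    negative cell, i.e. the requested similarity is infeasible for the
    given marginals.
    """
    if not (0.0 <= p1 <= 1.0 and 0.0 <= p2 <= 1.0):
        raise SimConfigurationError("activity probabilities must lie in [0, 1]")
    if not -1.0 <= similarity <= 1.0:
        raise SimConfigurationError("overlap similarity must lie in [-1, 1]")
    indep = p1 * p2
    p_double = indep + similarity * (min(p1, p2) - indep)
    cells = {
        "negative": 1.0 - p1 - p2 + p_double,
        "e1_only": p1 - p_double,
        "e2_only": p2 - p_double,
        "double": p_double,
    }
    bad = {k: v for k, v in cells.items() if v < -1e-12}
    if bad:
        raise SimConfigurationError(
            f"infeasible joint law for p1={p1}, p2={p2}, similarity={similarity}: "
            f"negative cells {bad}"
        )
    return {k: max(v, 0.0) for k, v in cells.items()}


def _default_p_e1() -> Dict[str, Dict[str, float]]:
    # Exploring-arm per-region marginals for epoch 1 (A1, Homer1a channel).
    # CA1 values follow the reported group proportions; cortical regions
    # are set to a common moderate level with no treatment effect.
    return {
        "CA1": {"control": 0.294, "QNP": 0.112},
        "ACC": {"control": 0.15, "QNP": 0.15},
        "OFC": {"control": 0.18, "QNP": 0.18},
        "mPFC": {"control": 0.15, "QNP": 0.15},
    }


def _default_p_e2() -> Dict[str, Dict[str, float]]:
    # Epoch 2 (A2, Arc channel) marginals.
    return {
        "CA1": {"control": 0.306, "QNP": 0.207},
        "ACC": {"control": 0.15, "QNP": 0.15},
        "OFC": {"control": 0.18, "QNP": 0.18},
        "mPFC": {"control": 0.15, "QNP": 0.15},
    }


def _default_n_animals() -> Dict[Tuple[str, str], int]:
    # Day-11 design cell sizes: 9 exploring + 6 home-cage QNP animals,
    # 9 exploring + 5 home-cage controls.
    return {
        ("QNP", "A1A2"): 9,
        ("control", "A1A2"): 9,
        ("QNP", "HC"): 6,
        ("control", "HC"): 5,
    }


@dataclass
class CatfishSimConfig:
    """Population, activity and feature parameters of the nucleus simulator.

    ``p_active_e1`` / ``p_active_e2`` map region -> treatment -> marginal
    activity probability for the arena-exploring cells; home-cage animals
    use ``hc_p_active`` in both epochs.  ``overlap_similarity`` is the
    target ensemble-overlap similarity of exploring animals (home-cage
    populations are generated at independence).
    """

    n_animals: Union[int, Mapping[Tuple[str, str], int]] = field(
        default_factory=_default_n_animals
    )
    # Sized so that after the mid-Z cut (20%) and glia exclusion a few
    # hundred neurons per animal x region remain analysable, matching the
    # scale of the quantified confocal data.
    n_nuclei_per_region: int = 1500
    regions: Sequence[str] = REGIONS
    p_active_e1: Mapping[str, Mapping[str, float]] = field(default_factory=_default_p_e1)
    p_active_e2: Mapping[str, Mapping[str, float]] = field(default_factory=_default_p_e2)
    hc_p_active: float = 0.03
    overlap_similarity: float = 0.3
    pos_intensity_dist: Tuple[float, float] = (25.0, 3.0)  # mean, sd (a.u.)
    neg_intensity_dist: Tuple[float, float] = (5.0, 2.0)
    glia_fraction: float = 0.15
    stack_slices: int = 21
    n_exemplars: int = 3  # weakest positives flagged per slide x region x channel
    animals_per_block: int = 6  # animals mounted together per slide block
    slides_per_block: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.n_animals, int):
            if self.n_animals <= 0:
                raise SimConfigurationError("n_animals must be positive")
            self.n_animals = {
                (t, e): self.n_animals for t in TREATMENTS for e in ENVIRONMENTS
            }
        if self.n_nuclei_per_region <= 0:
            raise SimConfigurationError("n_nuclei_per_region must be positive")
        if not 0.0 <= self.glia_fraction < 1.0:
            raise SimConfigurationError("glia_fraction must be in [0, 1)")
        if not 0.0 <= self.hc_p_active <= 1.0:
            raise SimConfigurationError("hc_p_active must be in [0, 1]")
        if self.stack_slices <= 0 or self.n_exemplars <= 0:
            raise SimConfigurationError("stack_slices and n_exemplars must be positive")
        # Validate every joint law used by the design up front so
        # generation fails loudly before anything is drawn.
        exploring_treatments = {
            t for (t, e), n in self.n_animals.items() if e == "A1A2" and n > 0
        }
        for region in self.regions:
            for trt in exploring_treatments:
                joint_activity_law(
                    self.p_active_e1[region][trt],
                    self.p_active_e2[region][trt],
                    self.overlap_similarity,
                )
        joint_activity_law(self.hc_p_active, self.hc_p_active, 0.0)


def _animal_roster(config: CatfishSimConfig) -> pd.DataFrame:
    """Animals with treatment/environment labels and slide-block assignment.

    Animals are interleaved exploring-first across blocks so that every
    slide block contains exploring animals (required for threshold
    exemplars, which only exploring animals provide).
    """
    animals = []
    for (trt, env), n in config.n_animals.items():
        for i in range(n):
            animals.append({"treatment": trt, "environment": env})
    # exploring first, then HC, then round-robin into blocks
    animals.sort(key=lambda a: (a["environment"] != "A1A2", a["treatment"]))
    n_blocks = max(1, int(np.ceil(len(animals) / config.animals_per_block)))
    rows = []
    for i, a in enumerate(animals):
        block = i % n_blocks
        rows.append(
            {
                "animal_id": f"{a['treatment']}_{a['environment']}_{i:02d}",
                "treatment": a["treatment"],
                "environment": a["environment"],
                "block": block,
            }
        )
    return pd.DataFrame(rows)


def simulate_catfish_population(config: CatfishSimConfig) -> pd.DataFrame:
    """Generate the per-nucleus feature table with latent ground truth.

    Returns one row per nucleus with the analysis schema (animal,
    treatment, environment, region, slide, z-centroid fraction, size,
    elongation, counterstain brightness, per-channel focus intensities,
    exemplar flags) plus latent columns ``latent_active_e1``,
    ``latent_active_e2`` and ``latent_glia`` for ground-truth checks.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    roster = _animal_roster(config)
    mu_pos, sd_pos = config.pos_intensity_dist
    mu_neg, sd_neg = config.neg_intensity_dist

    frames = []
    for row in roster.itertuples(index=False):
        for region in config.regions:
            n = config.n_nuclei_per_region
            if row.environment == "HC":
                law = joint_activity_law(config.hc_p_active, config.hc_p_active, 0.0)
            else:
                law = joint_activity_law(
                    config.p_active_e1[region][row.treatment],
                    config.p_active_e2[region][row.treatment],
                    config.overlap_similarity,
                )
            glia = rng.random(n) < config.glia_fraction
            cell = rng.choice(
                4,
                size=n,
                p=[law["negative"], law["e1_only"], law["e2_only"], law["double"]],
            )
            a1 = ((cell == 1) | (cell == 3)) & ~glia
            a2 = ((cell == 2) | (cell == 3)) & ~glia

            def draw(active: np.ndarray) -> np.ndarray:
                out = rng.normal(mu_neg, sd_neg, n)
                out[active] = rng.normal(mu_pos, sd_pos, int(active.sum()))
                return np.clip(out, 0.0, None)

            size = np.where(
                glia, rng.normal(90.0, 15.0, n), rng.normal(180.0, 30.0, n)
            ).clip(20.0, None)
            elong = np.where(
                glia, rng.normal(2.2, 0.3, n), rng.normal(1.3, 0.15, n)
            ).clip(1.0, None)
            brightness = np.where(
                glia, rng.normal(160.0, 20.0, n), rng.normal(100.0, 15.0, n)
            ).clip(0.0, None)
            slide_no = rng.integers(config.slides_per_block, size=n)
            frames.append(
                pd.DataFrame(
                    {
                        "animal_id": row.animal_id,
                        "treatment": row.treatment,
                        "environment": row.environment,
                        "region": region,
                        "slide_id": [f"B{row.block}S{s}" for s in slide_no],
                        "z_centroid_fraction": rng.random(n),
                        "size": size,
                        "elongation": elong,
                        "counterstain_brightness": brightness,
                        "intensity_e1_channel": draw(a1),
                        "intensity_e2_channel": draw(a2),
                        "latent_active_e1": a1,
                        "latent_active_e2": a2,
                        "latent_glia": glia,
                    }
                )
            )
    nuclei = pd.concat(frames, ignore_index=True)

    # Flag the k weakest true-active nuclei per slide x region x channel
    # among exploring-arm animals as threshold exemplars.
    for ch in ("e1", "e2"):
        flag = np.zeros(len(nuclei), dtype=bool)
        active = nuclei[f"latent_active_{ch}"] & (nuclei["environment"] == "A1A2")
        sub = nuclei[active]
        for (_, _), idx in sub.groupby(["slide_id", "region"]).groups.items():
            weakest = (
                nuclei.loc[idx, f"intensity_{ch}_channel"]
                .nsmallest(config.n_exemplars)
                .index
            )
            flag[nuclei.index.get_indexer(weakest)] = True
        nuclei[f"exemplar_weakest_{ch}"] = flag
    return nuclei
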