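"""Synthetic 33-muscle forearm/hand fixture.

A stand-in roster for a forearm + hand musculoskeletal model: 33 named
musculotendon actuators spanning 18 rotational DOFs (wrist
pronation-supination and extension-flexion, four thumb joints, and
metacarpophalangeal / proximal / distal interphalangeal joints of fingers
2-5), each tagged with one of seven functional categories (wrist
supinators / pronators / extensors / flexors, finger flexors / extensors,
thumb muscles).

The muscle -> DOF incidence below is SYNTHETIC: a plausible anatomical
assignment constrained so that the per-muscle DOF counts give exactly
674,937 fit-grid postures (sum of 9^d), 348,136 test-grid postures
(sum of 8^d) and 1,945,000 test-grid moment-arm values (sum of d * 8^d)
across the roster — the unique count distribution [5, 7, 7, 12, 1, 1]
for d = 1..6 satisfying all three totals.  Muscle geometries themselves
are random smooth oracles (see :func:`fixture_arm_model`), not anatomical
reconstructions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np

from .geometry import DofSpec, MuscleGeometryOracle, synth_muscle

#: The 18 modelled DOFs with their ranges of motion (radians).
ARM_DOFS: Dict[str, DofSpec] = {
    d.label: d
    for d in [
        DofSpec("ra_wr_s_p", (-1.5708, 1.5708)),   # forearm supination-pronation
        DofSpec("ra_wr_e_f", (-1.222, 1.222)),     # wrist extension-flexion
        DofSpec("ra_cmc1_f_e", (-0.52, 0.92)),     # thumb carpometacarpal flexion
        DofSpec("ra_cmc1_ab_ad", (-0.35, 0.70)),   # thumb CMC abduction-adduction
        DofSpec("ra_mcp1_f_e", (-0.26, 1.05)),     # thumb metacarpophalangeal
        DofSpec("ra_ip1_f_e", (-0.30, 1.40)),      # thumb interphalangeal
    ]
    + [DofSpec(f"ra_mcp{n}_f_e", (-0.44, 1.57)) for n in (2, 3, 4, 5)]
    + [DofSpec(f"ra_pip{n}_f_e", (0.0, 1.92)) for n in (2, 3, 4, 5)]
    + [DofSpec(f"ra_dip{n}_f_e", (0.0, 1.22)) for n in (2, 3, 4, 5)]
}

#: The seven functional categories.
FUNCTION_CATEGORIES = (
    "wrist supinators",
    "wrist pronators",
    "wrist extensors",
    "wrist flexors",
    "finger flexors",
    "finger extensors",
    "thumb muscles",
)

_WRIST = ("ra_wr_s_p", "ra_wr_e_f")
_THUMB_CMC = ("ra_cmc1_f_e", "ra_cmc1_ab_ad")


def _finger(n: int) -> Tuple[str, ...]:
    return (f"ra_mcp{n}_f_e", f"ra_pip{n}_f_e", f"ra_dip{n}_f_e")


#: muscle name -> (actuated DOF labels, functional category)
ARM_MUSCLES: Dict[str, Tuple[Tuple[str, ...], str]] = {
    # supinators / pronators cross only forearm rotation in this model
    "BIC_LO": (("ra_wr_s_p",), "wrist supinators"),
    "BIC_SH": (("ra_wr_s_p",), "wrist supinators"),
    "SUP": (("ra_wr_s_p",), "wrist supinators"),
    "PT": (("ra_wr_s_p",), "wrist pronators"),
    "PQ": (("ra_wr_s_p",), "wrist pronators"),
    # prime wrist movers cross both wrist DOFs
    "ECR_LO": (_WRIST, "wrist extensors"),
    "ECR_BR": (_WRIST, "wrist extensors"),
    "ECU": (_WRIST, "wrist extensors"),
    "FCR": (_WRIST, "wrist flexors"),
    "FCU": (_WRIST, "wrist flexors"),
    "PL": (_WRIST, "wrist flexors"),
    # extrinsic finger muscles: wrist flexion-extension + one finger's joints
    "FDS2": (("ra_wr_e_f",) + _finger(2), "finger flexors"),
    "FDS3": (("ra_wr_e_f",) + _finger(3), "finger flexors"),
    "FDS4": (("ra_wr_e_f",) + _finger(4), "finger flexors"),
    "FDS5": (("ra_wr_e_f",) + _finger(5), "finger flexors"),
    "FDP2": (("ra_wr_e_f",) + _finger(2), "finger flexors"),
    "FDP3": (("ra_wr_e_f",) + _finger(3), "finger flexors"),
    "FDP4": (("ra_wr_e_f",) + _finger(4), "finger flexors"),
    "FDP5": (("ra_wr_e_f",) + _finger(5), "finger flexors"),
    "ED2": (("ra_wr_e_f",) + _finger(2), "finger extensors"),
    "ED3": (("ra_wr_e_f",) + _finger(3), "finger extensors"),
    "ED4": (("ra_wr_e_f",) + _finger(4), "finger extensors"),
    "ED5": (("ra_wr_e_f",) + _finger(5), "finger extensors"),
    "EDM": (("ra_wr_e_f", "ra_mcp5_f_e"), "finger extensors"),
    "EIND": (("ra_wr_e_f", "ra_mcp2_f_e", "ra_pip2_f_e"), "finger extensors"),
    # thumb muscles
    "APL": (("ra_wr_s_p", "ra_wr_e_f", "ra_cmc1_ab_ad"), "thumb muscles"),
    "OP": (("ra_wr_e_f",) + _THUMB_CMC, "thumb muscles"),
    "APB": (_THUMB_CMC + ("ra_mcp1_f_e",), "thumb muscles"),
    "FPB": (_THUMB_CMC + ("ra_mcp1_f_e",), "thumb muscles"),
    "ADPT": (_THUMB_CMC + ("ra_mcp1_f_e",), "thumb muscles"),
    "EPB": (_THUMB_CMC + ("ra_mcp1_f_e",), "thumb muscles"),
    "EPL": (_WRIST + _THUMB_CMC + ("ra_mcp1_f_e",), "thumb muscles"),
    "FPL": (_WRIST + _THUMB_CMC + ("ra_mcp1_f_e", "ra_ip1_f_e"), "thumb muscles"),
}


@dataclass(frozen=True)
class ArmMuscle:
    """One fixture muscle: its name, geometry oracle, and category."""

    name: str
    oracle: MuscleGeometryOracle
    category: str

    @property
    def dof_labels(self) -> Tuple[str, ...]:
        return self.oracle.dof_labels


@dataclass(frozen=True)
class DatasetCounts:
    """Roster-wide posture/value counts implied by the DOF incidence."""

    fit_postures: int          # sum over muscles of 9^d
    test_postures: int         # sum over muscles of 8^d
    perturbation_lengths: int  # 10 noisy length samples per test posture
    perturbation_moments: int  # 10 noisy samples per test moment-arm value


def dof_incidence() -> Dict[str, Tuple[str, ...]]:
    """Muscle name -> actuated DOF labels."""
    return {name: dofs for name, (dofs, _cat) in ARM_MUSCLES.items()}


def categories() -> Dict[str, str]:
    """Muscle name -> functional category."""
    return {name: cat for name, (_dofs, cat) in ARM_MUSCLES.items()}


def dataset_point_counts(sets_per_posture: int = 10) -> DatasetCounts:
    """Grid and perturbation sample counts implied by the roster."""
    ds = [len(dofs) for dofs, _ in ARM_MUSCLES.values()]
    return DatasetCounts(
        fit_postures=sum(9 ** d for d in ds),
        test_postures=sum(8 ** d for d in ds),
        perturbation_lengths=sets_per_posture * sum(8 ** d for d in ds),
        perturbation_moments=sets_per_posture * sum(d * 8 ** d for d in ds),
    )


def _fixture_n_terms(d: int, rng: np.random.Generator) -> int:
    # mean polynomial size grows linearly with DOF count, ~7 terms per DOF
    return max(2, int(round(6.73 * d - 0.12)) + int(rng.integers(-2, 3)))


def fixture_arm_model(seed, wobble: float = 0.0) -> List[ArmMuscle]:
    """Build the 33-muscle synthetic roster.

    Each muscle gets an independent random polynomial geometry oracle over
    its own DOFs (child seeds spawned from ``seed``, so the roster is
    reproducible as a whole and per muscle).  ``wobble`` passes a smooth
    non-polynomial perturbation amplitude (mm) through to every oracle.
    """
    children = np.random.SeedSequence(seed).spawn(len(ARM_MUSCLES))
    roster = []
    for child, (name, (dof_labels, category)) in zip(children, ARM_MUSCLES.items()):
        rng = np.random.default_rng(child)
        d = len(dof_labels)
        n_terms = _fixture_n_terms(d, rng)
        oracle = synth_muscle(
            d, n_terms, rng,
            dofs=[ARM_DOFS[lbl] for lbl in dof_labels],
            wobble=wobble,
        )
        roster.append(ArmMuscle(name, oracle, category))
    return roster
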