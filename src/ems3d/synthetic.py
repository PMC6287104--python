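"""Deterministic synthetic fixtures: toy molecules, allele panels and
simulated donor-recipient cohorts.

Every stage of the pipeline can be exercised without external structure
downloads: toy molecules are small (~10 atom) charge patterns on one shared
neutral backbone frame, so superposition is trivial and all variants share
a single van der Waals surface; cohorts draw typings from a toy allele pool
and generate antibody outcomes from a logistic model with known
coefficients.  All randomness flows through one seeded generator passed
explicitly -- no global RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .matrix import EsdMatrix
from .score import HlaTyping, records_to_frame, score_pair
from .structure import Atom, Molecule

#: decoration sites shared by every toy variant (positions in Angstrom)
_SITES = np.array(
    [
        [0.0, 0.0, 2.2],   # top
        [0.0, 0.0, -2.2],  # bottom
        [2.6, 0.0, 0.0],   # +x flank
        [-2.6, 0.0, 0.0],  # -x flank
    ]
)

#: base charge patterns over the 4 sites: monopole pair (charge-swapped),
#: axial dipole pair (swapped), equatorial dipole, quadrupole
_BASE_PATTERNS = np.array(
    [
        [1.0, 0.0, 0.0, 0.0],
        [-1.0, 0.0, 0.0, 0.0],
        [1.0, -1.0, 0.0, 0.0],
        [-1.0, 1.0, 0.0, 0.0],
        [0.0, 0.0, 1.0, -1.0],
        [1.0, 1.0, -1.0, -1.0],
    ]
)


def make_toy_molecule(label: str, site_charges, radius: float = 1.5) -> Molecule:
    """One toy molecule: a neutral 6-atom ring plus 4 charged decoration sites."""
    atoms = []
    for i in range(6):
        ang = np.pi * i / 3.0
        atoms.append(
            Atom(
                name=f"C{i+1}", element="C",
                position=np.array([2.2 * np.cos(ang), 2.2 * np.sin(ang), 0.0]),
                charge=0.0, radius=1.7, residue_index=1, residue_name="TOY",
            )
        )
    for i, (pos, q) in enumerate(zip(_SITES, site_charges)):
        atoms.append(
            Atom(
                name=f"Q{i+1}", element="X", position=pos.copy(),
                charge=float(q), radius=radius, residue_index=1, residue_name="TOY",
            )
        )
    return Molecule(label, atoms)


def make_toy_panel(k: int, seed: int = 0) -> list[Molecule]:
    """``k`` toy molecules with varied charge patterns on one shared frame.

    The first six members are fixed canonical patterns (monopole and its
    charge-swapped twin, two axial dipole orientations, an equatorial
    dipole, a quadrupole); further members draw random site charges from
    the seeded generator.  Same seed, same molecules, byte for byte.
    """
    if k < 2:
        raise ValueError("panel needs k >= 2")
    rng = np.random.default_rng(seed)
    molecules = []
    for i in range(k):
        if i < len(_BASE_PATTERNS):
            charges = _BASE_PATTERNS[i]
        else:
            charges = np.round(rng.uniform(-1.0, 1.0, size=4), 3)
            if np.all(np.abs(charges) < 0.2):  # keep the field well above noise
                charges[0] = 1.0
        molecules.append(make_toy_molecule(f"toy{i:02d}", charges))
    return molecules


def toy_allele_names(labels: list[str], locus: str = "A") -> dict[str, str]:
    """Map toy molecule labels to synthetic two-field allele names at ``locus``."""
    return {lab: f"{locus}*{i + 1:02d}:01" for i, lab in enumerate(labels)}


def relabel_matrix(matrix: EsdMatrix, mapping: dict[str, str]) -> EsdMatrix:
    """ESD matrix with labels renamed through ``mapping``."""
    return EsdMatrix([mapping.get(l, l) for l in matrix.labels], matrix.values.copy())


@dataclass
class CohortSpec:
    """Study conditions for a simulated donor-recipient cohort.

    ``allele_pool`` maps each locus to the allele names that donors and
    recipients draw from (two draws per locus, with replacement, so
    homozygosity occurs naturally).  Antibody outcomes follow
    DSA ~ Bernoulli(expit(beta0 + beta1 * EMS-3D)); MFI values are
    log-normal around outcome-dependent medians, clipped to stay consistent
    with the binary call.  Lymphocyte dose (10^6 cells) is normal.
    """

    n_pairs: int = 2000
    allele_pool: dict[str, list[str]] = field(default_factory=dict)
    beta0: float = -2.0
    beta1: float = 8.0
    dose_mean: float = 200.0
    dose_sd: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        for locus, pool in self.allele_pool.items():
            if len(pool) < 2:
                raise ValueError(f"allele pool at locus {locus} needs >= 2 alleles")


def simulate_cohort(
    spec: CohortSpec, esd_lookup
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate typings, mismatch records and antibody outcomes.

    Returns (typings, mismatches, outcomes) as the same CSV schemas the
    real pipeline consumes.  Fixing ``spec.seed`` fixes every draw.
    """
    if not spec.allele_pool:
        raise ValueError("cohort spec has an empty allele pool")
    rng = np.random.default_rng(spec.seed)
    typing_rows = []
    outcome_rows = []
    mismatch_frames = []
    for p in range(spec.n_pairs):
        pair_id = f"pair{p:05d}"
        typings = {}
        for role in ("donor", "recipient"):
            names = []
            for locus, pool in spec.allele_pool.items():
                picks = rng.choice(pool, size=2, replace=True)
                names.extend(picks)
                typing_rows.append(
                    {"subject_id": f"{pair_id}-{role}", "role": role,
                     "locus": locus, "allele_1": picks[0], "allele_2": picks[1]}
                )
            typings[role] = HlaTyping.from_names(f"{pair_id}-{role}", names)
        dose = float(max(rng.normal(spec.dose_mean, spec.dose_sd), 1.0))
        records = score_pair(typings["donor"], typings["recipient"], esd_lookup)
        if records:
            frame = records_to_frame(records, f"{pair_id}-donor", f"{pair_id}-recipient")
            frame.insert(0, "pair_id", pair_id)
            mismatch_frames.append(frame)
        for rec in records:
            p_dsa = float(expit(spec.beta0 + spec.beta1 * rec.ems3d))
            dsa = bool(rng.random() < p_dsa)
            if dsa:
                mfi = max(2000.0, float(rng.lognormal(np.log(6000.0), 0.6)))
            else:
                mfi = min(1999.0, float(rng.lognormal(np.log(300.0), 1.0)))
            outcome_rows.append(
                {"pair_id": pair_id, "locus": rec.donor_allele.locus,
                 "donor_allele": rec.donor_allele.name, "ems3d": rec.ems3d,
                 "mfi": mfi, "dsa_2000": mfi >= 2000.0, "dsa_8000": mfi >= 8000.0,
                 "dose": dose}
            )
    typings_df = pd.DataFrame(typing_rows)
    mismatches_df = (
        pd.concat(mismatch_frames, ignore_index=True)
        if mismatch_frames
        else pd.DataFrame(
            columns=["pair_id", "donor_id", "recipient_id", "locus",
                     "donor_allele", "ems3d", "mode"]
        )
    )
    outcomes_df = pd.DataFrame(outcome_rows)
    return typings_df, mismatches_df, outcomes_df
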