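"""Radionuclide decay-chain constants and alpha-energy accounting.

For alpha-particle dosimetry the quantity that converts time-integrated
activity into absorbed energy is the mean energy emitted per nuclear
transition, Delta, in J/(Bq*s).  For a short-lived decay chain in secular
equilibrium every daughter decays where (and as often as) the parent does,
so Delta for the chain is the yield-weighted sum of the mean alpha energies
of all chain members, assigned per parent decay.  Only alpha particles are
counted; photon, electron and recoil energy are neglected, and the absorbed
fraction is handled downstream.

The constants table shipped with the package (``data/alpha_decay_data.csv``)
carries mean alpha energies and effective per-parent-decay yields for the
chains relevant to antibody-mediated alpha therapy:

* Ac-225 -> Fr-221 -> At-217 -> Bi-213 -> (Po-213 | Tl-209) -> Pb-209.
  Bi-213 branches 2.2% by alpha to Tl-209 and 97.8% by beta to Po-213,
  whose 8.38 MeV alpha is counted at that effective yield.
* the Bi-213 sub-chain on its own (free daughter redistributing to kidney);
* Pb-212 (beta) -> Bi-212 -> (Tl-208 | Po-212), alphas from Bi-212/Po-212;
* At-211 -> (Bi-207 by alpha | Po-211 by EC, then alpha).

Energies and yields are standard evaluated decay data rounded to the
precision given in the table; they are carried in MeV internally and
converted to joules exactly once at the chain-summation boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "MEV_TO_J",
    "BI213_HALF_LIFE_H",
    "AlphaEmission",
    "DecayChain",
    "Radionuclide",
    "decay_constant",
    "mean_alpha_energy_per_transition",
    "load_decay_data",
    "get_chain",
    "get_radionuclide",
    "available_nuclides",
]

#: Exact conversion factor (SI definition of the electronvolt).
MEV_TO_J = 1.602176634e-13

#: Physical half-life of Bi-213 in hours (45.6 min).
BI213_HALF_LIFE_H = 45.6 / 60.0


class DecayDataError(ValueError):
    """Raised for malformed or empty decay-chain constant data."""


@dataclass(frozen=True)
class AlphaEmission:
    """One alpha-emitting chain member, referenced to a single parent decay.

    Parameters
    ----------
    nuclide_label : str
        Chain member emitting the alpha (e.g. ``"Po-213"``).
    mean_energy_mev : float
        Mean alpha energy per emission, MeV.
    yield_per_decay : float
        Alphas emitted by this member per decay of the chain parent,
        in secular equilibrium (0..1).
    """

    nuclide_label: str
    mean_energy_mev: float
    yield_per_decay: float

    def __post_init__(self) -> None:
        if self.mean_energy_mev <= 0:
            raise DecayDataError(
                f"{self.nuclide_label}: mean alpha energy must be positive, "
                f"got {self.mean_energy_mev}"
            )
        if not 0.0 <= self.yield_per_decay <= 1.0:
            raise DecayDataError(
                f"{self.nuclide_label}: yield per parent decay must be in "
                f"[0, 1], got {self.yield_per_decay}"
            )


@dataclass(frozen=True)
class DecayChain:
    """A parent nuclide with the alpha emissions of its local chain."""

    parent_label: str
    physical_half_life_h: float
    emissions: tuple[AlphaEmission, ...]
    branch_note: str = ""

    def __post_init__(self) -> None:
        if self.physical_half_life_h <= 0:
            raise DecayDataError(
                f"{self.parent_label}: physical half-life must be positive"
            )

    @property
    def decay_constant_per_h(self) -> float:
        return decay_constant(self.physical_half_life_h)


@dataclass(frozen=True)
class Radionuclide:
    """Summary physical constants of a therapy nuclide.

    ``delta_alpha_j_per_bq_s`` is the chain Delta: the mean alpha energy
    emitted per nuclear transition of the parent, full local chain included.
    """

    label: str
    physical_half_life_h: float
    decay_constant_per_h: float
    delta_alpha_j_per_bq_s: float

    @classmethod
    def from_chain(cls, chain: DecayChain) -> "Radionuclide":
        return cls(
            label=chain.parent_label,
            physical_half_life_h=chain.physical_half_life_h,
            decay_constant_per_h=chain.decay_constant_per_h,
            delta_alpha_j_per_bq_s=mean_alpha_energy_per_transition(chain),
        )


def decay_constant(half_life_h: float) -> float:
    """Physical decay constant ln(2)/T_half in 1/h.

    Raises
    ------
    ValueError
        If ``half_life_h`` is not strictly positive.
    """
    if half_life_h <= 0:
        raise ValueError(f"half-life must be positive, got {half_life_h}")
    return math.log(2.0) / half_life_h


def mean_alpha_energy_per_transition(chain: DecayChain) -> float:
    """Mean alpha energy per nuclear transition, Delta, in J/(Bq*s).

    Sums ``yield * mean_energy`` over every alpha emission of the chain,
    assuming secular equilibrium, and converts MeV to joules.  The result is
    independent of the parent half-life and additive over chain members.

    Raises
    ------
    DecayDataError
        If the chain carries no alpha emissions.
    """
    if not chain.emissions:
        raise DecayDataError(
            f"decay chain {chain.parent_label!r} has no alpha emissions; "
            "cannot form a mean energy per transition"
        )
    total_mev = sum(e.yield_per_decay * e.mean_energy_mev for e in chain.emissions)
    return total_mev * MEV_TO_J


_BRANCH_NOTES = {
    "Ac-225": "Bi-213 branches 2.2% alpha to Tl-209, 97.8% beta to Po-213",
    "Bi-213": "2.2% alpha branch to Tl-209; Po-213 alpha at beta-branch yield",
    "Pb-212": "beta parent; alphas from Bi-212 (36%) and Po-212 (64%)",
    "At-211": "42% direct alpha; 58% EC to Po-211 followed by alpha",
}


def load_decay_data(path: str | Path | None = None) -> dict[str, DecayChain]:
    """Load decay chains from a constants CSV.

    The file needs columns ``nuclide,member,mean_energy_MeV,yield,half_life_h``;
    one row per chain member, where the row with ``member == nuclide`` carries
    the parent half-life.  Zero-yield rows mark non-alpha parents (e.g. the
    Pb-212 beta decay) and contribute no emission.  When ``path`` is None the
    packaged table is used.
    """
    if path is None:
        src = resources.files("alphadose").joinpath("data/alpha_decay_data.csv")
        with resources.as_file(src) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    required = {"nuclide", "member", "mean_energy_MeV", "yield", "half_life_h"}
    missing = required - set(df.columns)
    if missing:
        raise DecayDataError(f"decay data file missing columns: {sorted(missing)}")

    chains: dict[str, DecayChain] = {}
    for parent, grp in df.groupby("nuclide", sort=False):
        parent_rows = grp[grp["member"] == parent]
        if parent_rows.empty:
            raise DecayDataError(f"no parent row for chain {parent!r}")
        half_life = float(parent_rows["half_life_h"].iloc[0])
        emissions = tuple(
            AlphaEmission(
                nuclide_label=str(r["member"]),
                mean_energy_mev=float(r["mean_energy_MeV"]),
                yield_per_decay=float(r["yield"]),
            )
            for _, r in grp.iterrows()
            if float(r["yield"]) > 0.0
        )
        chains[str(parent)] = DecayChain(
            parent_label=str(parent),
            physical_half_life_h=half_life,
            emissions=emissions,
            branch_note=_BRANCH_NOTES.get(str(parent), ""),
        )
    return chains


_CHAIN_CACHE: dict[str, DecayChain] | None = None


def _chains() -> dict[str, DecayChain]:
    global _CHAIN_CACHE
    if _CHAIN_CACHE is None:
        _CHAIN_CACHE = load_decay_data()
    return _CHAIN_CACHE


def available_nuclides() -> tuple[str, ...]:
    """Labels of the chains in the packaged constants table."""
    return tuple(_chains())


def get_chain(label: str) -> DecayChain:
    """Packaged decay chain by parent label (e.g. ``"Ac-225"``)."""
    try:
        return _chains()[label]
    except KeyError:
        raise KeyError(
            f"unknown nuclide {label!r}; available: {sorted(_chains())}"
        ) from None


def get_radionuclide(label: str) -> Radionuclide:
    """Packaged :class:`Radionuclide` (half-life, lambda, Delta) by label."""
    return Radionuclide.from_chain(get_chain(label))
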