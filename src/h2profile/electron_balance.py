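"""Fermentation electron balances.

Available electrons (degree of reduction) per compound follow the standard
convention gamma = 4C + H - 2O - 3N, referenced to CO2, H2O and NH3 (so CO2
carries zero available electrons and H2 carries two).  The headline quantity
is the fraction of fermentation electrons disposed of as molecular hydrogen,
computed either against the substrate consumed (``substrate`` mode) or
against the recovered products including H2 (``products`` mode, default);
the two agree exactly when the electron balance closes.  Carbon and electron
recovery checks flag incomplete or inconsistent measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CompoundFormula",
    "FermentationMeasurement",
    "BUILTIN_COMPOUNDS",
    "available_electrons",
    "h2_electron_fraction",
    "recovery",
    "aggregate_replicates",
    "mol_h2_from_headspace",
    "load_measurements",
    "gamma_table",
]

R_L_ATM = 0.082057366  # L atm / (mol K)


@dataclass(frozen=True)
class CompoundFormula:
    name: str
    C: int = 0
    H: int = 0
    O: int = 0
    N: int = 0

    def __post_init__(self) -> None:
        if min(self.C, self.H, self.O, self.N) < 0:
            raise ValueError(f"{self.name}: negative atom counts")
        if self.C + self.H + self.O + self.N == 0:
            raise ValueError(f"{self.name}: formula has no atoms")


BUILTIN_COMPOUNDS: dict[str, CompoundFormula] = {
    c.name: c
    for c in (
        CompoundFormula("glucose", C=6, H=12, O=6),
        CompoundFormula("acetate", C=2, H=4, O=2),
        CompoundFormula("succinate", C=4, H=6, O=4),
        CompoundFormula("propionate", C=3, H=6, O=2),
        CompoundFormula("lactate", C=3, H=6, O=3),
        CompoundFormula("formate", C=1, H=2, O=2),
        CompoundFormula("butyrate", C=4, H=8, O=2),
        CompoundFormula("isobutyrate", C=4, H=8, O=2),
        CompoundFormula("ethanol", C=2, H=6, O=1),
        CompoundFormula("co2", C=1, O=2),
        CompoundFormula("h2", H=2),
    )
}


@dataclass
class FermentationMeasurement:
    substrate: CompoundFormula
    substrate_consumed_mol: float
    products: dict[str, float]  # compound name -> mol formed, H2 included
    replicate_id: str = "r1"
    compounds: dict[str, CompoundFormula] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.substrate_consumed_mol < 0:
            raise ValueError("substrate consumption must be non-negative")
        registry = {**BUILTIN_COMPOUNDS, **self.compounds}
        for name, mol in self.products.items():
            if mol < 0:
                raise ValueError(f"product {name}: negative amount")
            if name.lower() not in registry and name not in registry:
                raise KeyError(f"unknown compound {name!r}; add it to `compounds`")
        self.compounds = registry

    def formula(self, name: str) -> CompoundFormula:
        return self.compounds.get(name) or self.compounds[name.lower()]


def available_electrons(f: CompoundFormula) -> int:
    """Degree-of-reduction electron equivalents: 4C + H - 2O - 3N."""
    return 4 * f.C + f.H - 2 * f.O - 3 * f.N


def h2_electron_fraction(m: FermentationMeasurement, mode: str = "products") -> float:
    """Fraction of fermentation electrons disposed as H2.

    ``substrate`` mode divides H2 electrons by the electrons released from
    the consumed substrate; ``products`` mode divides by the electron sum of
    all recovered products (H2 included), which is robust to assimilation
    into biomass.
    """
    h2_mol = sum(
        mol for name, mol in m.products.items() if name.lower() == "h2"
    )
    h2_electrons = 2.0 * h2_mol
    if mode == "substrate":
        denom = available_electrons(m.substrate) * m.substrate_consumed_mol
        if denom <= 0:
            raise ValueError("substrate mode requires consumed substrate electrons > 0")
    elif mode == "products":
        denom = sum(
            available_electrons(m.formula(name)) * mol
            for name, mol in m.products.items()
        )
        if denom <= 0:
            raise ValueError("products mode requires recovered product electrons > 0")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return h2_electrons / denom


def recovery(m: FermentationMeasurement, include_co2: bool = True) -> tuple[float, float]:
    """(carbon_recovery, electron_recovery) of products over substrate.

    CO2 is included only when flagged (it carries carbon but no available
    electrons).  Values near 1 indicate a closed balance; <1 typically
    reflects assimilation into unmeasured biomass.
    """
    if m.substrate_consumed_mol <= 0:
        raise ValueError("recovery requires substrate consumption > 0")
    c_sub = m.substrate.C * m.substrate_consumed_mol
    e_sub = available_electrons(m.substrate) * m.substrate_consumed_mol
    c_prod = 0.0
    e_prod = 0.0
    for name, mol in m.products.items():
        f = m.formula(name)
        if not include_co2 and f.C > 0 and available_electrons(f) == 0:
            continue
        c_prod += f.C * mol
        e_prod += available_electrons(f) * mol
    carbon = c_prod / c_sub if c_sub > 0 else 0.0
    electron = e_prod / e_sub if e_sub > 0 else 0.0
    return carbon, electron


def aggregate_replicates(
    measurements: Sequence[FermentationMeasurement], mode: str = "products"
) -> dict[str, float]:
    """Mean and sd of the H2 electron fraction and recoveries across
    replicates; permutation-invariant."""
    if not measurements:
        raise ValueError("no measurements supplied")
    fractions = np.array([h2_electron_fraction(m, mode) for m in measurements])
    recs = np.array([recovery(m, include_co2=True) for m in measurements])
    return {
        "h2_electron_fraction_mean": float(fractions.mean()),
        "h2_electron_fraction_sd": float(fractions.std(ddof=1)) if len(fractions) > 1 else 0.0,
        "carbon_recovery_mean": float(recs[:, 0].mean()),
        "electron_recovery_mean": float(recs[:, 1].mean()),
        "n_replicates": float(len(measurements)),
    }


def mol_h2_from_headspace(ppm: float, volume_l: float, temp_k: float = 310.15) -> float:
    """Convert a headspace H2 mixing ratio (ppm) to mol via the ideal gas law
    at 1 atm total pressure."""
    if ppm < 0 or volume_l <= 0 or temp_k <= 0:
        raise ValueError("ppm must be >= 0; volume and temperature positive")
    total_mol = volume_l / (R_L_ATM * temp_k)
    return total_mol * ppm * 1e-6


def gamma_table(compounds: Mapping[str, CompoundFormula] | None = None) -> pd.DataFrame:
    """Full available-electron table, printed with every balance report."""
    compounds = dict(compounds or BUILTIN_COMPOUNDS)
    rows = [
        {
            "compound": f.name,
            "C": f.C,
            "H": f.H,
            "O": f.O,
            "N": f.N,
            "available_electrons": available_electrons(f),
        }
        for f in compounds.values()
    ]
    return pd.DataFrame(rows).set_index("compound")


def load_measurements(
    measurements_tsv: str | Path,
    registry_tsv: str | Path | None = None,
    substrate: str = "glucose",
) -> list[FermentationMeasurement]:
    """Read per-replicate measurements: columns replicate_id, compound, mol.

    The substrate row is identified by compound name; every other row is a
    product.  An optional registry TSV (name, C, H, O, N) extends the
    built-in compound table.
    """
    extra: dict[str, CompoundFormula] = {}
    if registry_tsv is not None:
        reg = pd.read_csv(registry_tsv, sep="\t")
        for row in reg.itertuples(index=False):
            extra[row.name] = CompoundFormula(
                row.name, C=int(row.C), H=int(row.H), O=int(row.O), N=int(row.N)
            )
    registry = {**BUILTIN_COMPOUNDS, **extra}
    if substrate not in registry:
        raise KeyError(f"substrate {substrate!r} not in compound registry")
    df = pd.read_csv(measurements_tsv, sep="\t")
    out = []
    for rep_id, group in df.groupby("replicate_id"):
        products = {}
        consumed = 0.0
        for row in group.itertuples(index=False):
            if row.compound == substrate:
                consumed = float(row.mol)
            else:
                products[row.compound] = float(row.mol)
        out.append(
            FermentationMeasurement(
                substrate=registry[substrate],
                substrate_consumed_mol=consumed,
                products=products,
                replicate_id=str(rep_id),
                compounds=extra,
            )
        )
    return out
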