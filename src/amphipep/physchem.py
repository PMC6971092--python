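"""Physicochemical annotation: hydrophobicity, average mass, charge and pI."""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .seqio import CANONICAL, ValidationError

WATER_MASS = 18.01528


def _data_path(name: str) -> Path:
    return Path(str(resources.files("amphipep").joinpath("data", name)))


def _read_two_column(path: Path, value_field: str) -> dict[str, float]:
    out: dict[str, float] = {}
    with open(path) as fh:
        rows = [r for r in fh if r.strip() and not r.startswith("#")]
    for row in csv.DictReader(rows, delimiter="\t"):
        out[row["residue"]] = float(row[value_field])
    return out


@dataclass(frozen=True)
class HydrophobicityScale:
    name: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        missing = CANONICAL - set(self.values)
        if missing:
            raise ValidationError(
                f"scale {self.name!r} is missing residues: {sorted(missing)}"
            )

    def __getitem__(self, residue: str) -> float:
        try:
            return self.values[residue]
        except KeyError:
            raise KeyError(
                f"no hydrophobicity value for residue {residue!r} in scale {self.name!r}"
            ) from None


def load_scale(name: str = "kyte_doolittle", path: str | Path | None = None) -> HydrophobicityScale:
    """Load a hydrophobicity scale; shipped default is Kyte-Doolittle."""
    p = Path(path) if path is not None else _data_path(f"{name}.tsv")
    return HydrophobicityScale(name=name, values=_read_two_column(p, "value"))


def kd_value(residue: str, scale: HydrophobicityScale | None = None) -> float:
    scale = scale or load_scale()
    return scale[residue]


_MASSES: dict[str, float] | None = None


def _masses() -> dict[str, float]:
    global _MASSES
    if _MASSES is None:
        _MASSES = _read_two_column(_data_path("residue_masses_average.tsv"), "mass")
    return _MASSES


def average_mass(sequence: str) -> float:
    """Average molecular mass of the peptide in g/mol (residues + one water)."""
    if not sequence:
        raise ValidationError("cannot compute mass of an empty sequence")
    masses = _masses()
    try:
        total = sum(masses[aa] for aa in sequence)
    except KeyError as exc:
        raise ValidationError(f"non-canonical residue {exc.args[0]!r} in sequence") from None
    return total + WATER_MASS


# ---------------------------------------------------------------------------
# charge and isoelectric point

_PKA_CACHE: dict[str, list[tuple[str, float, int]]] = {}


def load_pka_set(name: str = "lehninger") -> list[tuple[str, float, int]]:
    """Return [(group, pKa, charge_sign), ...] for the named set."""
    if name not in _PKA_CACHE:
        path = _data_path(f"pka_{name}.tsv")
        if not path.exists():
            raise ValidationError(f"unknown pKa set {name!r}")
        rows: list[tuple[str, float, int]] = []
        with open(path) as fh:
            lines = [r for r in fh if r.strip() and not r.startswith("#")]
        for row in csv.DictReader(lines, delimiter="\t"):
            rows.append((row["group"], float(row["pka"]), int(row["charge"])))
        _PKA_CACHE[name] = rows
    return _PKA_CACHE[name]


def net_charge(sequence: str, pH: float = 7.0, pka_set: str = "lehninger") -> float:
    """Henderson-Hasselbalch net charge over termini and ionizable side chains.

    Cysteines are treated as reduced (ionizable).
    """
    if not sequence:
        raise ValidationError("cannot compute charge of an empty sequence")
    if not 0.0 < pH < 14.0:
        raise ValidationError(f"pH {pH} outside (0, 14)")
    groups = load_pka_set(pka_set)
    counts = {"nterm": 1, "cterm": 1}
    for aa in sequence:
        counts[aa] = counts.get(aa, 0) + 1
    charge = 0.0
    for group, pka, sign in groups:
        n = counts.get(group, 0)
        if n == 0:
            continue
        if sign > 0:
            charge += n / (1.0 + 10.0 ** (pH - pka))
        else:
            charge -= n / (1.0 + 10.0 ** (pka - pH))
    return charge


def isoelectric_point(sequence: str, pka_set: str = "lehninger", tol: float = 0.01) -> float:
    """pH at which the net charge crosses zero, located by bisection.

    net_charge is monotonically non-increasing in pH, so bisection on (0, 14)
    is exact up to ``tol``.
    """
    lo, hi = 1e-6, 14.0 - 1e-6
    f_lo = net_charge(sequence, lo, pka_set)
    f_hi = net_charge(sequence, hi, pka_set)
    if f_lo < 0:
        return lo
    if f_hi > 0:
        return hi
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(sequence, mid, pka_set) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass(frozen=True)
class PeptideProperties:
    mw: float
    net_charge_ph7: float
    pI: float


def annotate(sequence: str, pka_set: str = "lehninger") -> PeptideProperties:
    return PeptideProperties(
        mw=average_mass(sequence),
        net_charge_ph7=net_charge(sequence, 7.0, pka_set),
        pI=isoelectric_point(sequence, pka_set),
    )
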