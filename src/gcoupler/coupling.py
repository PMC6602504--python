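"""Coupling indices from assay endpoints.

The shedding assay yields, per (receptor, chimeric Gα) pair, an Emax and an
EC50 from a sigmoidal concentration-response fit.  The per-receptor activity
ratio Emax/EC50 is normalised by its maximum over the Gα panel (relative
intrinsic activity, RAi) and log10-transformed into LogRAi, clamped to
[-2, 0]; LogRAi >= -1.0 calls a coupling.  This module owns that transform,
the binarisation, the chimeric-Gα construction rule (swap the last 6 backbone
residues) and the Gα family grouping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import (
    CHIMERA_TAIL_LENGTH,
    GALPHA_ALIASES,
    GALPHA_FAMILIES,
    LOGRAI_CUTOFF,
    LOGRAI_MAX,
    LOGRAI_MIN,
)
from .errors import IncompleteRecordError, InvalidAssayError, InvalidTailError


@dataclass(frozen=True)
class AssayRecord:
    """One dose-response summary: Emax and EC50 for a (receptor, Gα) pair."""

    receptor: str
    galpha: str
    emax: float
    ec50: float


@dataclass
class FamilyGrouping:
    """Mapping of Gα genes to the four families, with chimera alias expansion."""

    families: Mapping[str, str] = field(default_factory=lambda: dict(GALPHA_FAMILIES))
    aliases: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(GALPHA_ALIASES)
    )

    def family_of(self, galpha: str) -> str:
        return self.families[galpha]

    def members(self, family: str) -> list[str]:
        return [g for g, f in self.families.items() if f == family]

    def expand(self, name: str) -> list[str]:
        """Resolve a family symbol or gene symbol to modelled chimera genes."""
        if name in self.families:
            return [name]
        members = self.members(name)
        if not members:
            raise KeyError(f"unknown Gα gene or family: {name!r}")
        return members


def log_rai(records: Iterable[AssayRecord], galphas: Sequence[str] | None = None) -> pd.Series:
    """LogRAi vector over the Gα panel for one receptor's assay records.

    RAi = (Emax/EC50) / max over the panel; LogRAi = log10(RAi) clamped to
    [-2, 0].  The maximal Gα gets exactly 0.  Replicates for the same Gα are
    averaged on the Emax/EC50 ratio before normalisation.
    """
    records = list(records)
    if not records:
        raise IncompleteRecordError("no assay records supplied")
    receptors = {r.receptor for r in records}
    if len(receptors) != 1:
        raise IncompleteRecordError(
            f"log_rai expects records for one receptor, got {sorted(receptors)}"
        )
    ratios: dict[str, list[float]] = {}
    for r in records:
        if not (np.isfinite(r.emax) and np.isfinite(r.ec50)) or r.emax <= 0 or r.ec50 <= 0:
            raise InvalidAssayError(
                f"non-positive or non-finite endpoint for {r.receptor}/{r.galpha}: "
                f"emax={r.emax}, ec50={r.ec50}"
            )
        ratios.setdefault(r.galpha, []).append(r.emax / r.ec50)
    if galphas is None:
        galphas = sorted(ratios)
    missing = [g for g in galphas if g not in ratios]
    if missing:
        raise IncompleteRecordError(f"missing Gα records: {missing}")
    mean_ratio = pd.Series({g: float(np.mean(ratios[g])) for g in galphas}, dtype=float)
    rai = mean_ratio / mean_ratio.max()
    values = np.clip(np.log10(rai.to_numpy()), LOGRAI_MIN, LOGRAI_MAX)
    # The arg-max chimera is 0 by construction; enforce exactness against
    # floating-point noise in the division.
    values[np.argmax(mean_ratio.to_numpy())] = 0.0
    return pd.Series(values, index=list(galphas), name=next(iter(receptors)))


def log_rai_matrix(records: Iterable[AssayRecord], galphas: Sequence[str] | None = None) -> pd.DataFrame:
    """LogRAi matrix (receptor rows, Gα columns) from a full record set."""
    by_receptor: dict[str, list[AssayRecord]] = {}
    for r in records:
        by_receptor.setdefault(r.receptor, []).append(r)
    rows = [log_rai(recs, galphas) for recs in by_receptor.values()]
    return pd.DataFrame(rows)


def binarize(lograi: pd.DataFrame | pd.Series, cutoff: float = LOGRAI_CUTOFF):
    """Coupled iff LogRAi >= cutoff (boundary inclusive)."""
    return lograi >= cutoff


@dataclass
class CouplingMatrix:
    """Receptors × Gα LogRAi values with their binarised coupling labels."""

    lograi: pd.DataFrame
    cutoff: float = LOGRAI_CUTOFF

    def __post_init__(self) -> None:
        self.lograi.index.name = "receptor"
        values = self.lograi.to_numpy(dtype=float)
        if values.size and (values.min() < LOGRAI_MIN - 1e-12 or values.max() > LOGRAI_MAX + 1e-12):
            raise ValueError("LogRAi values must lie in [-2, 0]")

    @property
    def receptors(self) -> list[str]:
        return list(self.lograi.index)

    @property
    def galphas(self) -> list[str]:
        return list(self.lograi.columns)

    @property
    def labels(self) -> pd.DataFrame:
        return binarize(self.lograi, self.cutoff)

    @classmethod
    def from_records(
        cls,
        records: Iterable[AssayRecord],
        galphas: Sequence[str] | None = None,
        cutoff: float = LOGRAI_CUTOFF,
    ) -> "CouplingMatrix":
        return cls(log_rai_matrix(records, galphas), cutoff=cutoff)

    def to_tsv(self, path: str | Path) -> None:
        self.lograi.to_csv(path, sep="\t", index_label="receptor")

    @classmethod
    def from_tsv(cls, path: str | Path, cutoff: float = LOGRAI_CUTOFF) -> "CouplingMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col="receptor"), cutoff=cutoff)


def build_chimera(backbone: str, donor_tail: str) -> str:
    """Replace the last 6 residues of ``backbone`` with ``donor_tail``.

    Models the chimeric Gα constructs: a GNAQ backbone carrying another Gα's
    C-terminal hexapeptide, which confers that Gα's receptor recognition.
    """
    if len(donor_tail) != CHIMERA_TAIL_LENGTH:
        raise InvalidTailError(
            f"donor tail must have exactly {CHIMERA_TAIL_LENGTH} residues, "
            f"got {len(donor_tail)}"
        )
    if len(backbone) <= CHIMERA_TAIL_LENGTH:
        raise InvalidTailError("backbone must be longer than the swapped tail")
    return backbone[:-CHIMERA_TAIL_LENGTH] + donor_tail


def read_assay_tsv(path: str | Path) -> list[AssayRecord]:
    """Read assay records from TSV (columns: receptor, galpha, emax, ec50)."""
    df = pd.read_csv(path, sep="\t")
    return [
        AssayRecord(str(r.receptor), str(r.galpha), float(r.emax), float(r.ec50))
        for r in df.itertuples(index=False)
    ]


def write_assay_tsv(records: Iterable[AssayRecord], path: str | Path) -> None:
    pd.DataFrame([r.__dict__ for r in records]).to_csv(path, sep="\t", index=False)
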