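"""In-silico mutation design: coupling-switching substitution scans.

Residues of the query that map to positions statistically associated with
the selected couplings (the union of the positional features of the chosen
Gα models) are each substituted into the 19 alternative amino acids; the
mutant sequence is re-predicted end to end and, per Gα, two probability
differences are recorded: ΔP(coupled) = P(mut) − P(WT) (does the mutation
gain a wanted coupling?) and ΔP(uncoupled) = P(WT) − P(mut) (does it lose an
unwanted one?).  Candidates pass when the relevant difference reaches the
threshold (default 0.25) and are ranked by their best qualifying difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import AMINO_ACIDS, DESIGN_THRESHOLD
from .errors import GcouplerError
from .features import map_bw
from .hmm import align_to_profile, sanitize
from .pipeline import TrainedModels, predict


@dataclass
class MutationCandidate:
    """One substitution with its per-Gα probability shifts."""

    position: int  # 1-based on the raw input sequence
    bw_label: str
    wt: str
    new: str
    dp_coupled: dict[str, float] = field(default_factory=dict)
    dp_uncoupled: dict[str, float] = field(default_factory=dict)
    rank_score: float = -np.inf
    passes: bool = False

    @property
    def notation(self) -> str:
        return f"{self.wt}{self.position}{self.new}"


def scannable_positions(
    sequence: str,
    models: TrainedModels,
    galphas: set[str],
) -> dict[int, int]:
    """1-based query positions mapping to the selected Gα's feature columns.

    Returns {query position: alignment column} for residues aligned to the
    union of positional-feature columns of the chosen models.
    """
    pa = align_to_profile(sequence, models.base_hmm, score_floor=models.score_floor)
    columns: set[int] = set()
    for g in galphas:
        columns.update(models.models[g].schema.positional)
    cols = models.base_hmm.consensus_columns
    out: dict[int, int] = {}
    for qi, ci in pa.column_of_residue.items():
        col = int(cols[ci])
        if col in columns:
            out[qi + 1] = col
    return out


def scan_mutations(
    sequence: str,
    models: TrainedModels,
    target_galphas: set[str] | None = None,
    avoid_galphas: set[str] | None = None,
    threshold: float = DESIGN_THRESHOLD,
) -> list[MutationCandidate]:
    """Systematic 19-substitution scan at coupling-associated positions.

    ``target_galphas`` are couplings to gain (shortlist on ΔP(coupled) >=
    threshold), ``avoid_galphas`` couplings to lose (ΔP(uncoupled) >=
    threshold).  The returned list contains every scanned candidate, passing
    ones first, ordered by descending best qualifying difference; ties break
    on position then residue for determinism.
    """
    target_galphas = set(target_galphas or ())
    avoid_galphas = set(avoid_galphas or ())
    if not target_galphas and not avoid_galphas:
        raise GcouplerError("select at least one target or avoid Gα")
    unknown = (target_galphas | avoid_galphas) - set(models.galphas)
    if unknown:
        raise GcouplerError(f"no trained model for: {sorted(unknown)}")

    sequence = sanitize(sequence)
    wt_report = predict({"WT": sequence}, models)
    p_wt = wt_report.probabilities.loc["WT"]

    positions = scannable_positions(sequence, models, target_galphas | avoid_galphas)
    candidates: list[MutationCandidate] = []
    mutants: dict[str, str] = {}
    meta: dict[str, tuple[int, int, str, str]] = {}
    for pos, col in sorted(positions.items()):
        wt = sequence[pos - 1]
        for new in AMINO_ACIDS:
            if new == wt:
                continue
            name = f"{wt}{pos}{new}"
            mutants[name] = sequence[: pos - 1] + new + sequence[pos:]
            meta[name] = (pos, col, wt, new)
    if not mutants:
        return []

    mut_report = predict(mutants, models)
    for name, (pos, col, wt, new) in meta.items():
        p_mut = mut_report.probabilities.loc[name]
        dp_c = {g: float(p_mut[g] - p_wt[g]) for g in models.galphas}
        dp_u = {g: -v for g, v in dp_c.items()}
        qualifying = [dp_c[g] for g in target_galphas] + [dp_u[g] for g in avoid_galphas]
        best = max(qualifying)
        candidates.append(
            MutationCandidate(
                position=pos,
                bw_label=map_bw(col, models.region_map),
                wt=wt,
                new=new,
                dp_coupled=dp_c,
                dp_uncoupled=dp_u,
                rank_score=best,
                passes=best >= threshold,
            )
        )
    candidates.sort(key=lambda c: (-c.rank_score, c.position, c.new))
    return candidates


def candidates_to_frame(candidates: list[MutationCandidate]) -> pd.DataFrame:
    """Tabulate a scan result (one row per candidate, ΔP columns per Gα)."""
    rows = []
    for c in candidates:
        row = {
            "mutation": c.notation, "position": c.position, "bw": c.bw_label,
            "rank_score": c.rank_score, "passes": c.passes,
        }
        for g, v in c.dp_coupled.items():
            row[f"dP_coupled:{g}"] = v
        for g, v in c.dp_uncoupled.items():
            row[f"dP_uncoupled:{g}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
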