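"""Per-Gα discriminative features from coupled vs not-coupled profile pairs.

For each Gα the training alignment splits into coupled and not-coupled
sub-alignments, each summarised as a profile HMM.  Features are then:

* **positional** — consensus columns (in both profiles) where the 20 paired
  residue bit-scores differ (Wilcoxon signed-rank, p <= alpha); a query
  contributes its residue's bit-score from *both* profiles at each one;
* **indel** — columns consensus in exactly one profile, contributing the one
  available bit-score;
* **loop** — ICL3 / C-terminal length and residue counts whose distributions
  differ between classes (two-sided rank-sum, p < alpha);
* **structural** — permutation Z-scores of suitable template interfaces.

A query with no residue at a selected column gets the *least-conserved*
sentinel: the minimum residue bit-score of that column.  Helix positions are
reported in Ballesteros/Weinstein numbering (x.50 anchored); positions
outside the helices fall back to the raw profile column in parentheses.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .constants import AMINO_ACIDS, DEFAULT_PSEUDOCOUNT, DEFAULT_SYMFRAC, GAP_CHARS
from .errors import SchemaMismatchError
from .hmm import ProfileAlignment, ProfileHMM, build_profile

_LOOP_REGIONS = ("ICL3", "Cterm")


@dataclass
class RegionMap:
    """Receptor segment layout over alignment columns.

    ``segments`` maps a segment name (TM1..TM7, ICL3, Cterm) to a half-open
    column interval; an end of ``None`` means "to the end of the sequence".
    ``anchors`` give the x.50 reference column per helix for B/W numbering.
    """

    segments: dict[str, tuple[int, int | None]]
    anchors: dict[str, int] = field(default_factory=dict)

    def segment_of(self, column: int) -> str | None:
        for name, (s, e) in self.segments.items():
            if column >= s and (e is None or column < e):
                return name
        return None

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("segment\tstart\tend\tanchor\n")
            for name, (s, e) in self.segments.items():
                anchor = self.anchors.get(name, "")
                fh.write(f"{name}\t{s}\t{'' if e is None else e}\t{anchor}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RegionMap":
        segments: dict[str, tuple[int, int | None]] = {}
        anchors: dict[str, int] = {}
        with open(path) as fh:
            next(fh)
            for line in fh:
                name, s, e, anchor = line.rstrip("\n").split("\t")
                segments[name] = (int(s), None if e == "" else int(e))
                if anchor != "":
                    anchors[name] = int(anchor)
        return cls(segments=segments, anchors=anchors)


def map_bw(column: int, region_map: RegionMap) -> str:
    """Ballesteros/Weinstein label of an alignment column.

    Columns inside helix ``TMh`` are labelled ``h.(50 + offset)`` relative to
    the helix anchor; anything else is the raw 1-based column in parentheses.
    """
    seg = region_map.segment_of(column)
    if seg is not None and seg.startswith("TM") and seg in region_map.anchors:
        helix = seg[2:]
        return f"{helix}.{50 + column - region_map.anchors[seg]}"
    return f"({column + 1})"


# ---------------------------------------------------------------------------
# schema derivation

def _paired_bitscore_pvalue(coupled: ProfileHMM, uncoupled: ProfileHMM,
                            column: int) -> float:
    """Signed-rank p-value of the 20 paired residue bit-scores at a column.

    Zero differences are dropped (Wilcoxon convention); the exact null
    distribution is used when the non-zero |differences| are tie-free,
    otherwise the normal approximation.
    """
    diff = coupled.bitscore_row(column) - uncoupled.bitscore_row(column)
    nonzero = diff[diff != 0.0]
    if nonzero.size == 0:
        return 1.0
    method = "exact" if np.unique(np.abs(nonzero)).size == nonzero.size else "approx"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.wilcoxon(nonzero, zero_method="wilcox", method=method,
                             alternative="two-sided")
    return float(res.pvalue)


def select_significant_positions(
    coupled: ProfileHMM,
    uncoupled: ProfileHMM,
    alpha: float = 0.05,
) -> list[int]:
    """Columns consensus in both profiles whose bit-score profiles differ
    (signed-rank p <= alpha, boundary inclusive)."""
    shared = sorted(
        set(map(int, coupled.consensus_columns)) & set(map(int, uncoupled.consensus_columns))
    )
    if not shared:
        warnings.warn("no shared consensus columns; empty positional schema")
        return []
    return [c for c in shared if _paired_bitscore_pvalue(coupled, uncoupled, c) <= alpha]


def detect_indels(coupled: ProfileHMM, uncoupled: ProfileHMM) -> list[tuple[int, str]]:
    """Columns consensus in exactly one profile, tagged with their side."""
    cset = set(map(int, coupled.consensus_columns))
    uset = set(map(int, uncoupled.consensus_columns))
    out = [(c, "coupled") for c in cset - uset] + [(c, "uncoupled") for c in uset - cset]
    return sorted(out)


def region_residues_from_row(row: str, region_map: RegionMap, region: str) -> str:
    """Residues of one gapped alignment row falling inside a segment."""
    s, e = region_map.segments[region]
    stretch = row[s:] if e is None else row[s:e]
    return "".join(ch for ch in stretch if ch not in GAP_CHARS)


def select_loop_features(
    rows: Sequence[str],
    labels: Sequence[bool],
    region_map: RegionMap,
    alpha: float = 0.05,
    use_frequencies: bool = False,
) -> tuple[list[str], list[tuple[str, str]]]:
    """Retain loop length / composition features separating the classes.

    Candidates are, per region (ICL3 and C-term): its residue-stretch length
    and the 20 per-residue counts (frequencies behind ``use_frequencies``).
    A candidate is retained iff the two-sided rank-sum test between coupled
    and not-coupled values gives p < alpha (strict).  Zero-variance
    candidates are dropped.
    """
    y = np.asarray(labels, dtype=bool)
    lengths_retained: list[str] = []
    comp_retained: list[tuple[str, str]] = []
    for region in _LOOP_REGIONS:
        if region not in region_map.segments:
            continue
        stretches = [region_residues_from_row(r, region_map, region) for r in rows]
        if all(len(s) == 0 for s in stretches):
            warnings.warn(f"region {region} empty in every sequence; skipped")
            continue
        lengths = np.array([len(s) for s in stretches], dtype=float)
        if _ranksum_keep(lengths, y, alpha):
            lengths_retained.append(region)
        for aa in AMINO_ACIDS:
            counts = np.array([s.count(aa) for s in stretches], dtype=float)
            if use_frequencies:
                with np.errstate(invalid="ignore", divide="ignore"):
                    counts = np.where(lengths > 0, counts / np.maximum(lengths, 1), 0.0)
            if _ranksum_keep(counts, y, alpha):
                comp_retained.append((region, aa))
    return lengths_retained, comp_retained


def _ranksum_keep(values: np.ndarray, y: np.ndarray, alpha: float) -> bool:
    if np.ptp(values) == 0.0:
        return False
    res = stats.ranksums(values[y], values[~y])
    return bool(res.pvalue < alpha)


@dataclass
class FeatureSchema:
    """Frozen, ordered description of one Gα's feature space."""

    galpha: str
    positional: list[int]  # alignment columns, two bit-score values each
    indels: list[tuple[int, str]]  # (column, "coupled"|"uncoupled")
    loop_length: list[str]  # retained region names
    loop_composition: list[tuple[str, str]]  # (region, residue)
    structural: list[str]  # template identifiers
    bw_labels: dict[int, str] = field(default_factory=dict)

    @property
    def feature_names(self) -> list[str]:
        names: list[str] = []
        for c in self.positional:
            names.append(f"pos:{c}:coupled")
            names.append(f"pos:{c}:uncoupled")
        for c, side in self.indels:
            names.append(f"indel:{c}:{side}")
        for region in self.loop_length:
            names.append(f"len:{region}")
        for region, aa in self.loop_composition:
            names.append(f"comp:{region}:{aa}")
        for tid in self.structural:
            names.append(f"struct:{tid}")
        return names

    @property
    def width(self) -> int:
        return (2 * len(self.positional) + len(self.indels) + len(self.loop_length)
                + len(self.loop_composition) + len(self.structural))

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "galpha": self.galpha,
            "positional": self.positional,
            "indels": [[c, side] for c, side in self.indels],
            "loop_length": self.loop_length,
            "loop_composition": [[r, a] for r, a in self.loop_composition],
            "structural": self.structural,
            "bw_labels": {str(k): v for k, v in self.bw_labels.items()},
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "FeatureSchema":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(
            galpha=d["galpha"],
            positional=[int(c) for c in d["positional"]],
            indels=[(int(c), side) for c, side in d["indels"]],
            loop_length=list(d["loop_length"]),
            loop_composition=[(r, a) for r, a in d["loop_composition"]],
            structural=list(d["structural"]),
            bw_labels={int(k): v for k, v in d["bw_labels"].items()},
        )


# ---------------------------------------------------------------------------
# query-side residue view and feature vector extraction

@dataclass
class AlignedResidues:
    """Uniform view of a receptor in alignment-column coordinates."""

    residues: dict[int, str]  # alignment column -> residue
    regions: dict[str, str]  # region name -> residue stretch (inserts included)

    @classmethod
    def from_row(cls, row: str, region_map: RegionMap) -> "AlignedResidues":
        residues = {c: ch for c, ch in enumerate(row) if ch not in GAP_CHARS}
        regions = {
            name: region_residues_from_row(row, region_map, name)
            for name in _LOOP_REGIONS
            if name in region_map.segments
        }
        return cls(residues=residues, regions=regions)

    @classmethod
    def from_profile_alignment(
        cls,
        pa: ProfileAlignment,
        base_hmm: ProfileHMM,
        region_map: RegionMap,
    ) -> "AlignedResidues":
        cols = base_hmm.consensus_columns
        residues = {int(cols[ci]): aa for ci, aa in pa.residue_map().items()}
        inserts = pa.insert_residues()
        regions: dict[str, str] = {}
        for name in _LOOP_REGIONS:
            if name not in region_map.segments:
                continue
            s, e = region_map.segments[name]
            chunks: list[tuple[int, str]] = []
            for col, aa in residues.items():
                if col >= s and (e is None or col < e):
                    chunks.append((col, aa))
            for after_ci, q_idxs in inserts.items():
                anchor = -1 if after_ci < 0 else int(cols[after_ci])
                if anchor >= s - 1 and (e is None or anchor < e):
                    chunks.append((anchor, "".join(pa.query[q] for q in sorted(q_idxs))))
            regions[name] = "".join(txt for _, txt in sorted(chunks))
        return cls(residues=residues, regions=regions)


def extract_features(
    ar: AlignedResidues,
    schema: FeatureSchema,
    coupled: ProfileHMM,
    uncoupled: ProfileHMM,
    structural_scores: Mapping[str, float] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Feature vector of one receptor under a frozen schema.

    Returns (values, provenance) where provenance marks each entry as
    ``observed`` or ``sentinel`` (missing residue -> least-conserved score;
    missing structural score -> 0).
    """
    values: list[float] = []
    prov: list[str] = []
    for c in schema.positional:
        if not (coupled.is_consensus(c) and uncoupled.is_consensus(c)):
            raise SchemaMismatchError(
                f"schema column {c} is not consensus in both profiles"
            )
        aa = ar.residues.get(c)
        if aa is not None:
            values += [coupled.bitscore(c, aa), uncoupled.bitscore(c, aa)]
            prov += ["observed", "observed"]
        else:
            values += [coupled.min_bitscore(c), uncoupled.min_bitscore(c)]
            prov += ["sentinel", "sentinel"]
    for c, side in schema.indels:
        hmm = coupled if side == "coupled" else uncoupled
        aa = ar.residues.get(c)
        if aa is not None:
            values.append(hmm.bitscore(c, aa))
            prov.append("observed")
        else:
            values.append(hmm.min_bitscore(c))
            prov.append("sentinel")
    for region in schema.loop_length:
        values.append(float(len(ar.regions.get(region, ""))))
        prov.append("observed")
    for region, aa in schema.loop_composition:
        values.append(float(ar.regions.get(region, "").count(aa)))
        prov.append("observed")
    for tid in schema.structural:
        if structural_scores is not None and tid in structural_scores:
            values.append(float(structural_scores[tid]))
            prov.append("observed")
        else:
            values.append(0.0)
            prov.append("sentinel")
    return np.asarray(values, dtype=float), prov


# ---------------------------------------------------------------------------
# estimator

class CouplingFeatureExtractor(BaseEstimator, TransformerMixin):
    """Derive one Gα's feature schema from a labelled alignment and featurize.

    ``fit`` takes the training alignment rows (gapped strings sharing one
    column space) and boolean coupling labels; it builds the coupled and
    not-coupled profile HMMs, runs the positional / indel / loop selections
    and freezes a :class:`FeatureSchema`.  ``transform`` maps alignment rows
    (or :class:`AlignedResidues`) to the schema's feature matrix.

    Parameters
    ----------
    galpha : identifier of the Gα this extractor models.
    alpha_positional, alpha_loop : significance thresholds of the positional
        signed-rank (inclusive) and loop rank-sum (strict) selections.
    symfrac, pseudocount : profile construction parameters.
    region_map : segment layout used for loop features and B/W labels.
    """

    def __init__(
        self,
        galpha: str = "G",
        alpha_positional: float = 0.05,
        alpha_loop: float = 0.05,
        symfrac: float = DEFAULT_SYMFRAC,
        pseudocount: float = DEFAULT_PSEUDOCOUNT,
        region_map: RegionMap | None = None,
        structural_templates: Sequence[str] = (),
    ):
        self.galpha = galpha
        self.alpha_positional = alpha_positional
        self.alpha_loop = alpha_loop
        self.symfrac = symfrac
        self.pseudocount = pseudocount
        self.region_map = region_map
        self.structural_templates = structural_templates

    def fit(self, X: Sequence[str], y: Sequence[bool]) -> "CouplingFeatureExtractor":
        rows = list(X)
        labels = np.asarray(y, dtype=bool)
        if len(rows) != len(labels):
            raise ValueError("X and y lengths differ")
        if labels.all() or not labels.any():
            raise ValueError("both coupled and not-coupled sequences are required")
        coupled_rows = [r for r, keep in zip(rows, labels) if keep]
        uncoupled_rows = [r for r, keep in zip(rows, labels) if not keep]
        self.coupled_hmm_ = build_profile(coupled_rows, self.symfrac, self.pseudocount)
        self.uncoupled_hmm_ = build_profile(uncoupled_rows, self.symfrac, self.pseudocount)
        positional = select_significant_positions(
            self.coupled_hmm_, self.uncoupled_hmm_, self.alpha_positional
        )
        indels = detect_indels(self.coupled_hmm_, self.uncoupled_hmm_)
        region_map = self.region_map or RegionMap(segments={})
        if region_map.segments:
            loop_len, loop_comp = select_loop_features(
                rows, labels, region_map, self.alpha_loop
            )
        else:
            loop_len, loop_comp = [], []
        bw = {c: map_bw(c, region_map) for c in positional}
        self.schema_ = FeatureSchema(
            galpha=self.galpha,
            positional=positional,
            indels=indels,
            loop_length=loop_len,
            loop_composition=loop_comp,
            structural=list(self.structural_templates),
            bw_labels=bw,
        )
        return self

    def transform(
        self,
        X: Sequence[str | AlignedResidues],
        structural_scores: Sequence[Mapping[str, float]] | None = None,
    ) -> np.ndarray:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "schema_")
        region_map = self.region_map or RegionMap(segments={})
        matrix = np.empty((len(X), self.schema_.width))
        for i, item in enumerate(X):
            ar = (item if isinstance(item, AlignedResidues)
                  else AlignedResidues.from_row(item, region_map))
            scores = structural_scores[i] if structural_scores is not None else None
            matrix[i], _ = extract_features(
                ar, self.schema_, self.coupled_hmm_, self.uncoupled_hmm_, scores
            )
        return matrix

    def get_feature_names_out(self, input_features=None):
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "schema_")
        return np.asarray(self.schema_.feature_names, dtype=object)
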