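"""End-to-end training and prediction across the Gα panel.

``train_models`` turns a labelled receptor alignment into a
:class:`TrainedModels` artifact: one base family profile (for aligning new
queries), and per Gα a frozen feature schema, the coupled/not-coupled
profile pair and a fitted logistic-regression bundle.  ``predict`` aligns
FASTA queries to the base profile, featurizes them per schema and reports
coupling probabilities with per-feature attributions.  Artifacts carry a
fingerprint (hash of the schema and profile serializations) that is checked
at predict time to prevent silent drift between schema and weights.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import (
    CouplingClassifier,
    ModelBundle,
    TrainingConfig,
    compute_metrics,
    feature_relevance,
)
from .constants import LOGRAI_CUTOFF, PROBABILITY_THRESHOLD
from .coupling import binarize
from .errors import FingerprintMismatchError, GcouplerError, MutationError, NoMatchError
from .features import (
    AlignedResidues,
    CouplingFeatureExtractor,
    FeatureSchema,
    RegionMap,
)
from .hmm import ProfileHMM, align_to_profile, build_profile

_MUTATION_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z])$")


@dataclass
class GalphaModel:
    """Everything needed to score one Gα: schema, profiles, weights."""

    schema: FeatureSchema
    coupled_hmm: ProfileHMM
    uncoupled_hmm: ProfileHMM
    bundle: ModelBundle


@dataclass
class TrainedModels:
    """The deployable artifact of a training run."""

    base_hmm: ProfileHMM
    region_map: RegionMap
    models: dict[str, GalphaModel]
    score_floor: float = 0.0
    fingerprint: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if not self.fingerprint:
            self.fingerprint = self.compute_fingerprint()

    @property
    def galphas(self) -> list[str]:
        return list(self.models)

    def compute_fingerprint(self) -> str:
        # hash the canonical text serializations so the fingerprint survives
        # a save/load round trip
        h = hashlib.sha256()
        h.update(self.base_hmm.serialize().encode())
        for g in sorted(self.models):
            m = self.models[g]
            h.update(g.encode())
            h.update(m.schema.to_json().encode())
            h.update(m.coupled_hmm.serialize().encode())
            h.update(m.uncoupled_hmm.serialize().encode())
        return h.hexdigest()[:16]

    # -- persistence -----------------------------------------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.base_hmm.to_tsv(directory / "base_hmm.tsv")
        self.region_map.to_tsv(directory / "regions.tsv")
        for g, m in self.models.items():
            m.schema.to_json(directory / f"{g}.schema.json")
            m.coupled_hmm.to_tsv(directory / f"{g}.coupled_hmm.tsv")
            m.uncoupled_hmm.to_tsv(directory / f"{g}.uncoupled_hmm.tsv")
            m.bundle.to_json(directory / f"{g}.model.json")
        manifest = {
            "galphas": self.galphas,
            "fingerprint": self.fingerprint,
            "score_floor": self.score_floor,
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, directory: str | Path) -> "TrainedModels":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        base = ProfileHMM.from_tsv(directory / "base_hmm.tsv")
        regions = RegionMap.from_tsv(directory / "regions.tsv")
        models = {}
        for g in manifest["galphas"]:
            models[g] = GalphaModel(
                schema=FeatureSchema.from_json(directory / f"{g}.schema.json"),
                coupled_hmm=ProfileHMM.from_tsv(directory / f"{g}.coupled_hmm.tsv"),
                uncoupled_hmm=ProfileHMM.from_tsv(directory / f"{g}.uncoupled_hmm.tsv"),
                bundle=ModelBundle.from_json(directory / f"{g}.model.json"),
            )
        obj = cls(
            base_hmm=base, region_map=regions, models=models,
            score_floor=float(manifest.get("score_floor", 0.0)),
            fingerprint=manifest["fingerprint"],
        )
        if obj.compute_fingerprint() != manifest["fingerprint"]:
            raise FingerprintMismatchError(
                f"artifacts in {directory} do not match their recorded fingerprint"
            )
        return obj


@dataclass
class TrainingReport:
    """Diagnostics of a training run: CV AUC, refit metrics, relevance."""

    metrics: pd.DataFrame  # per Gα: cv_auc_mean, cv_auc_sd, C, refit metrics
    relevance: pd.DataFrame  # feature × Gα weight matrix (union of features)


def train_models(
    rows: Sequence[str],
    labels: pd.DataFrame,
    region_map: RegionMap,
    config: TrainingConfig | None = None,
    galphas: Sequence[str] | None = None,
    score_floor: float = 0.0,
    structural_scores: pd.DataFrame | None = None,
) -> tuple[TrainedModels, TrainingReport]:
    """Fit the full per-Gα model suite from a labelled alignment.

    ``rows`` are gapped alignment rows (shared column space) in the same
    order as ``labels`` (receptors × Gα booleans).  Gα whose labels are
    single-class are skipped with a warning column in the report.

    ``structural_scores`` (receptors × template ids, permutation Z-scores)
    optionally adds interface features: a template joins a Gα's schema only
    when its coupled and uncoupled score distributions differ
    (:func:`~gcoupler.interprets.template_suitability`).
    """
    from .interprets import template_suitability

    config = config or TrainingConfig()
    if len(rows) != len(labels):
        raise GcouplerError("alignment and label matrix sizes differ")
    galphas = list(galphas) if galphas is not None else list(labels.columns)
    if structural_scores is not None:
        structural_scores = structural_scores.loc[labels.index]
    base_hmm = build_profile(rows)
    models: dict[str, GalphaModel] = {}
    metric_rows = []
    relevance: dict[str, pd.Series] = {}
    for g in galphas:
        y = labels[g].to_numpy(dtype=bool)
        n_pos = int(y.sum())
        if min(n_pos, len(y) - n_pos) < config.n_folds:
            metric_rows.append({"galpha": g, "status": "skipped: class too small"})
            continue
        suitable: list[str] = []
        row_scores = None
        if structural_scores is not None:
            suitable = [
                tid for tid in structural_scores.columns
                if template_suitability(
                    structural_scores.loc[y, tid].tolist(),
                    structural_scores.loc[~y, tid].tolist(),
                )
            ]
            row_scores = [
                {tid: float(structural_scores.iloc[i][tid]) for tid in suitable}
                for i in range(len(labels))
            ]
        extractor = CouplingFeatureExtractor(
            galpha=g, region_map=region_map, structural_templates=suitable
        ).fit(rows, y)
        matrix = extractor.transform(rows, structural_scores=row_scores)
        clf = CouplingClassifier(
            C_grid=config.c_grid, n_folds=config.n_folds,
            n_repeats=config.n_repeats, class_weight=config.class_weighting,
            scaling=config.scaling, random_state=config.seed,
        ).fit(matrix, y)
        names = extractor.schema_.feature_names
        bundle = ModelBundle.from_estimator(clf, g, names)
        models[g] = GalphaModel(
            schema=extractor.schema_,
            coupled_hmm=extractor.coupled_hmm_,
            uncoupled_hmm=extractor.uncoupled_hmm_,
            bundle=bundle,
        )
        refit = compute_metrics(bundle.predict_proba(matrix), y)
        metric_rows.append({
            "galpha": g, "status": "ok", "n_features": len(names),
            "C": clf.C_, "cv_auc_mean": clf.cv_auc_mean_,
            "cv_auc_sd": clf.cv_auc_sd_, **refit.to_dict(),
        })
        relevance[g] = pd.Series(dict(zip(names, bundle.weights)))
    trained = TrainedModels(
        base_hmm=base_hmm, region_map=region_map, models=models,
        score_floor=score_floor,
    )
    report = TrainingReport(
        metrics=pd.DataFrame(metric_rows).set_index("galpha"),
        relevance=pd.DataFrame(relevance).fillna(0.0),
    )
    return trained, report


@dataclass
class PredictionReport:
    """Per-receptor per-Gα probabilities with attributions."""

    probabilities: pd.DataFrame  # receptors × Gα, NaN for non-matching queries
    attributions: pd.DataFrame  # long form: receptor, galpha, feature, value
    unmatched: list[str]
    fingerprint: str
    threshold: float = PROBABILITY_THRESHOLD

    @property
    def coupled(self) -> pd.DataFrame:
        return self.probabilities > self.threshold

    def to_tsv(self, path: str | Path) -> None:
        self.probabilities.to_csv(path, sep="\t", index_label="receptor",
                                  float_format="%.6f")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "fingerprint": self.fingerprint,
            "threshold": self.threshold,
            "unmatched": self.unmatched,
            "predictions": {
                r: {
                    g: None if np.isnan(p) else round(float(p), 6)
                    for g, p in row.items()
                }
                for r, row in self.probabilities.iterrows()
            },
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def featurize_query(
    sequence: str,
    models: TrainedModels,
    structural_scores: Mapping[str, float] | None = None,
) -> dict[str, np.ndarray]:
    """Align one query to the base profile and featurize it per Gα schema."""
    pa = align_to_profile(sequence, models.base_hmm, score_floor=models.score_floor)
    ar = AlignedResidues.from_profile_alignment(pa, models.base_hmm, models.region_map)
    from .features import extract_features

    out = {}
    for g, m in models.models.items():
        vec, _ = extract_features(
            ar, m.schema, m.coupled_hmm, m.uncoupled_hmm, structural_scores
        )
        out[g] = vec
    return out


def predict(
    sequences: Mapping[str, str],
    models: TrainedModels,
    expected_fingerprint: str | None = None,
    structural_scores: Mapping[str, Mapping[str, float]] | None = None,
) -> PredictionReport:
    """Coupling probabilities for a set of receptor sequences.

    Sequences that do not align to the family profile above the reporting
    floor are listed in ``unmatched`` with NaN probabilities (non-7TM
    verdict).  Attribution rows satisfy Σ contributions + intercept =
    logit(P) per (receptor, Gα).
    """
    if not sequences:
        raise GcouplerError("no input sequences")
    if expected_fingerprint is not None and expected_fingerprint != models.fingerprint:
        raise FingerprintMismatchError(
            f"model fingerprint {models.fingerprint} != expected {expected_fingerprint}"
        )
    galphas = models.galphas
    prob_rows = {}
    attr_rows = []
    unmatched = []
    for name, seq in sequences.items():
        try:
            feats = featurize_query(
                seq, models,
                structural_scores.get(name) if structural_scores else None,
            )
        except NoMatchError:
            unmatched.append(name)
            prob_rows[name] = {g: np.nan for g in galphas}
            continue
        row = {}
        for g in galphas:
            bundle = models.models[g].bundle
            row[g] = float(bundle.predict_proba(feats[g])[0])
            contrib = bundle.contributions(feats[g])[0]
            for fname, value in zip(bundle.feature_names, contrib):
                attr_rows.append(
                    {"receptor": name, "galpha": g, "feature": fname,
                     "contribution": float(value)}
                )
        prob_rows[name] = row
    probabilities = pd.DataFrame.from_dict(prob_rows, orient="index")[galphas]
    probabilities.index = list(sequences)
    attributions = pd.DataFrame(
        attr_rows, columns=["receptor", "galpha", "feature", "contribution"]
    )
    return PredictionReport(
        probabilities=probabilities,
        attributions=attributions,
        unmatched=unmatched,
        fingerprint=models.fingerprint,
    )


# ---------------------------------------------------------------------------
# mutations

def parse_mutation(text: str) -> tuple[str, int, str]:
    """Parse "A10V" into (wt, 1-based position, new)."""
    m = _MUTATION_RE.match(text.strip())
    if not m:
        raise MutationError(f"malformed mutation {text!r}; expected e.g. A10V")
    return m.group(1).upper(), int(m.group(2)), m.group(3).upper()


def apply_mutations(
    sequence: str, mutations: Iterable[str | tuple[str, int, str]]
) -> str:
    """Apply point substitutions in "XnY" notation (1-based positions).

    Every mutation is validated: positions must fall inside the sequence and
    the stated wild-type residue must match; all violations are reported
    together in one error.
    """
    seq = list(sequence)
    problems = []
    for mut in mutations:
        wt, pos, new = parse_mutation(mut) if isinstance(mut, str) else mut
        if not 1 <= pos <= len(seq):
            problems.append(f"{wt}{pos}{new}: position out of range (1..{len(seq)})")
            continue
        if seq[pos - 1].upper() != wt:
            problems.append(
                f"{wt}{pos}{new}: wild-type mismatch (sequence has {seq[pos - 1]})"
            )
            continue
        seq[pos - 1] = new
    if problems:
        raise MutationError("; ".join(problems))
    return "".join(seq)


def compare_known(
    report: PredictionReport,
    known: pd.DataFrame,
    cutoff: float = LOGRAI_CUTOFF,
) -> pd.DataFrame:
    """Annotate predictions with user-supplied known couplings.

    ``known`` rows are receptors; values may be LogRAi (binarised at the
    cutoff) or boolean calls.  Receptors absent from the table stay blank;
    duplicated, contradictory rows are both kept and flagged.
    """
    frames = []
    duplicated = set(known.index[known.index.duplicated()])
    for receptor in report.probabilities.index:
        for g in report.probabilities.columns:
            p = report.probabilities.loc[receptor, g]
            entry = {
                "receptor": receptor, "galpha": g,
                "probability": p,
                "predicted": "" if np.isnan(p) else ("coupled" if p > report.threshold
                                                     else "not-coupled"),
                "known": "", "flag": "",
            }
            if receptor in known.index and g in known.columns:
                values = known.loc[[receptor], g].tolist()
                calls = []
                for v in values:
                    if pd.isna(v):
                        continue
                    if isinstance(v, (bool, np.bool_)):
                        calls.append("coupled" if v else "not-coupled")
                    else:
                        calls.append("coupled" if binarize(float(v), cutoff)
                                     else "not-coupled")
                entry["known"] = "|".join(calls)
                if receptor in duplicated and len(set(calls)) > 1:
                    entry["flag"] = "contradictory"
            else:
                entry["flag"] = "no-record" if receptor not in known.index else ""
            frames.append(entry)
    return pd.DataFrame(frames)
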