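"""Synthetic 7TM-like families with planted coupling determinants.

The generator emulates the training data the coupling predictor expects: an
alignable receptor family (seven "helix" blocks of consensus columns, a
variable third intracellular loop, a variable C-terminal tail), per-receptor
coupling labels for a panel of Gα proteins, and noisy Emax/EC50 assay
endpoints consistent with those labels.

Labels are drawn first (deterministically from the seed); determinant
residues are then planted conditioned on the label: a truth-coupled receptor
carries the favoured residue at a determinant column with probability
``1/20 + effect_size * 19/20`` while uncoupled receptors draw uniformly, so
the between-class frequency margin is ``effect_size * 19/20`` in expectation
and vanishes at zero effect.

Non-determinant consensus columns draw from a *class-balanced* background:
each column has one preferred residue (chosen once per family) carried with
probability ``conservation`` and a uniform residue otherwise, identically in
both classes.  The per-column conservation is what anchors profile
alignment, as in real 7TM families; because it is identical across classes
it introduces no composition confounder into the selection tests.
Determinant columns keep a uniform background in the uncoupled class, so the
planted margin is exactly ``effect_size * 19/20``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import AA_INDEX, AMINO_ACIDS, CHIMERA_GALPHAS, DEFAULT_SYMFRAC, N_AA
from .coupling import AssayRecord
from .errors import InvalidSpecError
from .features import RegionMap
from .interprets import TemplateComplex

_HELICES = tuple(f"TM{i}" for i in range(1, 8))


@dataclass(frozen=True)
class Determinant:
    """A planted coupling determinant: one favoured residue at one column."""

    column: int  # consensus column index, 0-based
    residue: str
    effect_size: float
    galpha: str


@dataclass(frozen=True)
class LoopLengthEffect:
    """Class-dependent ICL3 length: Poisson means per coupling label."""

    galpha: str
    mean_coupled: float
    mean_uncoupled: float


@dataclass
class FamilySpec:
    """Parameters of one synthetic receptor family."""

    n_receptors: int = 144
    n_consensus_columns: int = 60
    determinants: tuple[Determinant, ...] = ()
    loop_length_effect: LoopLengthEffect | None = None
    indel_rate: float = 0.02
    coupled_fraction: float = 0.5
    conservation: float = 0.6
    galphas: tuple[str, ...] | None = None
    region_map: RegionMap | None = None
    icl3_mean_length: float = 6.0
    cterm_mean_length: float = 8.0
    symfrac: float = DEFAULT_SYMFRAC
    seed: int = 0

    def resolved_galphas(self) -> tuple[str, ...]:
        if self.galphas is not None:
            return tuple(self.galphas)
        seen: list[str] = []
        for d in self.determinants:
            if d.galpha not in seen:
                seen.append(d.galpha)
        if self.loop_length_effect and self.loop_length_effect.galpha not in seen:
            seen.append(self.loop_length_effect.galpha)
        return tuple(seen)

    def validate(self) -> None:
        if self.n_consensus_columns < 40:
            raise InvalidSpecError("need at least 40 consensus columns")
        if self.n_receptors < 2:
            raise InvalidSpecError("need at least 2 receptors")
        if not 0.0 < self.coupled_fraction < 1.0:
            raise InvalidSpecError("coupled_fraction must be in (0, 1)")
        if not self.resolved_galphas():
            raise InvalidSpecError("no Gα targets: give determinants or galphas")
        region_map = self.consensus_region_map()
        seen_cols = set()
        for d in self.determinants:
            if not 0.0 <= d.effect_size <= 1.0:
                raise InvalidSpecError(f"effect size out of [0,1]: {d}")
            if d.residue not in AA_INDEX:
                raise InvalidSpecError(f"unknown favoured residue: {d}")
            if d.column in seen_cols:
                raise InvalidSpecError(f"duplicate determinant column {d.column}")
            seen_cols.add(d.column)
            if not any(
                s <= d.column < e for s, e in region_map.segments.values() if e is not None
            ):
                raise InvalidSpecError(
                    f"determinant column {d.column} outside the region map"
                )

    def consensus_region_map(self) -> RegionMap:
        """Region map in consensus-column coordinates (before insert pools)."""
        if self.region_map is not None:
            return self.region_map
        return default_region_map(self.n_consensus_columns)


def default_region_map(n_columns: int) -> RegionMap:
    """Seven equal helix blocks with a 2-column ICL3 stub between TM5 and TM6."""
    n_icl3 = 2
    per_tm, extra = divmod(n_columns - n_icl3, 7)
    if per_tm < 4:
        raise InvalidSpecError("too few columns for a 7-helix layout")
    sizes = [per_tm + (1 if i < extra else 0) for i in range(7)]
    segments: dict[str, tuple[int, int | None]] = {}
    anchors: dict[str, int] = {}
    pos = 0
    for i, h in enumerate(_HELICES):
        start, end = pos, pos + sizes[i]
        segments[h] = (start, end)
        anchors[h] = (start + end) // 2
        pos = end
        if h == "TM5":
            segments["ICL3"] = (pos, pos + n_icl3)
            pos += n_icl3
    segments["Cterm"] = (pos, None)
    return RegionMap(segments=segments, anchors=anchors)


@dataclass
class SyntheticFamily:
    """Output of :func:`generate_family`: alignment plus ground truth."""

    ids: list[str]
    rows: list[str]  # gapped alignment rows, uniform length
    labels: pd.DataFrame  # receptors × Gα, boolean truth
    region_map: RegionMap  # in original (gapped) column coordinates
    consensus_columns: np.ndarray  # original column indices of consensus columns
    spec: FamilySpec

    @property
    def sequences(self) -> dict[str, str]:
        return {i: r.replace("-", "") for i, r in zip(self.ids, self.rows)}

    def write_alignment(self, path: str | Path) -> None:
        from .hmm import write_alignment_fasta

        write_alignment_fasta(self.ids, self.rows, path)

    def write_labels(self, path: str | Path) -> None:
        self.labels.astype(int).to_csv(path, sep="\t", index_label="receptor")


def _spread_insert_block(lengths: np.ndarray, rng: np.random.Generator,
                         n: int) -> tuple[int, list[np.ndarray]]:
    """Place variable-length insert runs into a pool of low-occupancy columns.

    Each receptor's run occupies a sorted random subset of the pool, so no
    pool column reaches the 0.5 consensus threshold; the pool widens and the
    placement is redrawn in the unlikely event one does.
    """
    max_len = int(lengths.max(initial=0))
    if max_len == 0:
        return 0, [np.empty(0, dtype=int) for _ in lengths]
    width = max(2 * max_len, int(np.ceil(2.5 * lengths.mean())) + 1, 4)
    for _ in range(20):
        placements = [np.sort(rng.choice(width, size=int(k), replace=False))
                      for k in lengths]
        occupancy = np.zeros(width, dtype=int)
        for p in placements:
            occupancy[p] += 1
        if occupancy.max(initial=0) < 0.5 * n:
            return width, placements
        width = int(np.ceil(width * 1.5)) + 1
    raise InvalidSpecError("could not place insert block below consensus threshold")


def generate_family(spec: FamilySpec) -> SyntheticFamily:
    """Generate an aligned synthetic family with truth coupling labels."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, C = spec.n_receptors, spec.n_consensus_columns
    galphas = spec.resolved_galphas()
    cons_regions = spec.consensus_region_map()

    ids = [f"R{i:04d}" for i in range(n)]
    labels = pd.DataFrame(
        {g: rng.random(n) < spec.coupled_fraction for g in galphas}, index=ids
    )

    # consensus residues: conserved class-balanced background at non-determinant
    # columns, uniform at determinant columns, determinants planted on coupled rows
    residues = rng.integers(0, N_AA, size=(n, C))
    preferred = rng.integers(0, N_AA, size=C)
    conserve = rng.random(size=(n, C)) < spec.conservation
    det_col_set = {d.column for d in spec.determinants}
    for c in range(C):
        if c not in det_col_set:
            residues[conserve[:, c], c] = preferred[c]
    for d in spec.determinants:
        u = rng.random(n)
        planted = labels[d.galpha].to_numpy() & (u < d.effect_size)
        residues[planted, d.column] = AA_INDEX[d.residue]

    # class-linked ICL3 length, Poisson around the configured means
    if spec.loop_length_effect is not None:
        eff = spec.loop_length_effect
        lam = np.where(labels[eff.galpha].to_numpy(),
                       eff.mean_coupled, eff.mean_uncoupled)
    else:
        lam = np.full(n, spec.icl3_mean_length)
    icl3_lengths = rng.poisson(lam)
    cterm_lengths = rng.poisson(spec.cterm_mean_length, size=n)

    icl3_width, icl3_place = _spread_insert_block(icl3_lengths, rng, n)
    cterm_width, cterm_place = _spread_insert_block(cterm_lengths, rng, n)

    # random deletion runs (gap runs) at non-determinant consensus columns
    deletion = np.zeros((n, C), dtype=bool)
    det_cols = {d.column for d in spec.determinants}
    free_cols = [c for c in range(C) if c not in det_cols]
    col_del_counts = np.zeros(C, dtype=int)
    cap = max(1, int(0.4 * n))
    for r in range(n):
        if rng.random() < spec.indel_rate and free_cols:
            start = int(rng.choice(free_cols))
            run = int(rng.integers(1, 4))
            for c in range(start, min(start + run, C)):
                if c in det_cols or col_del_counts[c] + 1 >= cap:
                    break
                deletion[r, c] = True
                col_del_counts[c] += 1

    # assemble original-column layout: consensus blocks with the ICL3 pool
    # spliced after the ICL3 consensus stub and the C-term pool at the end
    icl3_seg = cons_regions.segments["ICL3"]
    icl3_after = icl3_seg[1] - 1  # last ICL3 consensus column
    total_cols = C + icl3_width + cterm_width
    orig_of_consensus = np.empty(C, dtype=int)
    for c in range(C):
        orig_of_consensus[c] = c if c <= icl3_after else c + icl3_width
    icl3_pool_start = icl3_after + 1
    cterm_pool_start = C + icl3_width

    icl3_fill = rng.integers(0, N_AA, size=(n, max(icl3_width, 1)))
    cterm_fill = rng.integers(0, N_AA, size=(n, max(cterm_width, 1)))

    rows = []
    for r in range(n):
        row = ["-"] * total_cols
        for c in range(C):
            if not deletion[r, c]:
                row[orig_of_consensus[c]] = AMINO_ACIDS[residues[r, c]]
        for k, p in enumerate(icl3_place[r]):
            row[icl3_pool_start + p] = AMINO_ACIDS[icl3_fill[r, k]]
        for k, p in enumerate(cterm_place[r]):
            row[cterm_pool_start + p] = AMINO_ACIDS[cterm_fill[r, k]]
        rows.append("".join(row))

    # region map translated into original-column coordinates
    segments: dict[str, tuple[int, int | None]] = {}
    anchors: dict[str, int] = {}
    for name, (s, e) in cons_regions.segments.items():
        if name == "ICL3":
            segments[name] = (int(orig_of_consensus[s]), icl3_pool_start + icl3_width)
        elif name == "Cterm":
            segments[name] = (cterm_pool_start, None)
        else:
            segments[name] = (int(orig_of_consensus[s]), int(orig_of_consensus[e - 1]) + 1)
    for h, a in cons_regions.anchors.items():
        anchors[h] = int(orig_of_consensus[a])
    region_map = RegionMap(segments=segments, anchors=anchors)

    return SyntheticFamily(
        ids=ids,
        rows=rows,
        labels=labels,
        region_map=region_map,
        consensus_columns=orig_of_consensus,
        spec=spec,
    )


def simulate_assay(
    truth: pd.DataFrame,
    dynamic_range: float = 100.0,
    noise_sd: float = 0.15,
    seed: int = 0,
) -> list[AssayRecord]:
    """Emit Emax/EC50 endpoints consistent with a truth label matrix.

    Coupled (receptor, Gα) pairs get an activity ratio at the receptor
    maximum; uncoupled pairs sit exactly ``dynamic_range``-fold lower before
    noise.  Log-normal noise of width ``noise_sd`` (decades) multiplies the
    ratio; the ratio is then split into an EC50 (log-uniform in a molar-ish
    range) and the matching Emax.
    """
    if dynamic_range <= 1:
        raise InvalidSpecError("dynamic_range must exceed 1")
    rng = np.random.default_rng(seed)
    records: list[AssayRecord] = []
    for receptor in truth.index:
        for galpha in truth.columns:
            ratio = 1.0 if bool(truth.loc[receptor, galpha]) else 1.0 / dynamic_range
            if noise_sd > 0:
                ratio *= 10.0 ** rng.normal(0.0, noise_sd)
            ec50 = 10.0 ** rng.uniform(-8.5, -6.5)
            records.append(
                AssayRecord(str(receptor), str(galpha), float(ratio * ec50), float(ec50))
            )
    return records


def generate_toy_complex(n_contacts: int, seed: int = 0) -> TemplateComplex:
    """A small receptor/Gα interface fixture for the statistical-potential layer.

    Random chain sequences, ``n_contacts`` distinct cross-chain residue
    contacts, and a dense symmetric log-odds-like potential populated for all
    400 ordered residue pairs.  Chain alignments are the identity.
    """
    if n_contacts < 1:
        raise InvalidSpecError("need at least one contact")
    rng = np.random.default_rng(seed)
    len_r = max(10, n_contacts + 5)
    len_g = max(8, n_contacts + 3)
    receptor = "".join(AMINO_ACIDS[i] for i in rng.integers(0, N_AA, len_r))
    galpha = "".join(AMINO_ACIDS[i] for i in rng.integers(0, N_AA, len_g))
    pairs = rng.choice(len_r * len_g, size=n_contacts, replace=False)
    contacts = sorted((int(p // len_g), int(p % len_g)) for p in pairs)
    table = rng.normal(0.0, 1.0, size=(N_AA, N_AA))
    potential = (table + table.T) / 2.0
    return TemplateComplex(
        template_id=f"toy{seed}",
        contacts=contacts,
        potential=potential,
        receptor_chain=receptor,
        galpha_chain=galpha,
    )


def default_family_spec(seed: int = 0) -> FamilySpec:
    """A study-scale default family: 144 receptors, the 11-chimera panel,
    two strong determinants for a representative Gα of each family and a
    class-linked ICL3 length for GNAS."""
    determinants = (
        Determinant(column=8, residue="W", effect_size=0.9, galpha="GNAS"),
        Determinant(column=22, residue="K", effect_size=0.9, galpha="GNAS"),
        Determinant(column=14, residue="D", effect_size=0.9, galpha="GNAI1"),
        Determinant(column=35, residue="F", effect_size=0.9, galpha="GNAI1"),
        Determinant(column=39, residue="R", effect_size=0.9, galpha="GNAQ"),
        Determinant(column=51, residue="Y", effect_size=0.9, galpha="GNAQ"),
        Determinant(column=18, residue="L", effect_size=0.9, galpha="GNA12"),
        Determinant(column=47, residue="H", effect_size=0.9, galpha="GNA12"),
    )
    return FamilySpec(
        n_receptors=144,
        n_consensus_columns=60,
        determinants=determinants,
        loop_length_effect=LoopLengthEffect("GNAS", 28.0, 10.0),
        galphas=CHIMERA_GALPHAS,
        seed=seed,
    )
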