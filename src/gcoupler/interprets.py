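"""Interface fitness scores from residue-pair statistical potentials.

Given a known receptor/Gα complex structure (a "template"), the raw score of
a candidate receptor/Gα pair is the sum of a 20x20 residue-pair potential
over the template's interface contacts, read through alignments of the two
query sequences to the template chains.  Significance comes from a
permutation null: the receptor's aligned residues are shuffled over its
aligned positions, giving a Z-score and an add-one permutation p-value.
A template is a *suitable* feature for a given Gα when the Z-scores of
coupled and uncoupled training receptors differ (two-sided rank-sum test).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .constants import AA_INDEX, AMINO_ACIDS, N_AA
from .errors import GcouplerError

#: Guard against degenerate (constant) permutation nulls.
SD_FLOOR = 1e-9


@dataclass
class TemplateComplex:
    """One template interface: contacts in template coordinates + potential."""

    template_id: str
    contacts: list[tuple[int, int]]  # (receptor position, Gα position), 0-based
    potential: np.ndarray  # (20, 20), ordered (receptor residue, Gα residue)
    receptor_chain: str
    galpha_chain: str

    def __post_init__(self) -> None:
        self.potential = np.asarray(self.potential, dtype=float)
        if self.potential.shape != (N_AA, N_AA):
            raise GcouplerError("potential table must be 20x20")
        if not np.all(np.isfinite(self.potential)):
            raise GcouplerError("potential table must be finite")
        for rp, gp in self.contacts:
            if not (0 <= rp < len(self.receptor_chain) and 0 <= gp < len(self.galpha_chain)):
                raise GcouplerError(f"contact ({rp},{gp}) outside template chains")


@dataclass
class StructScore:
    """Raw interface score with its permutation Z-score and p-value."""

    raw: float
    z: float
    p: float
    n_perm: int


def identity_alignment(sequence: str) -> dict[int, int]:
    """Query position -> template position for an ungapped identical mapping."""
    return {i: i for i in range(len(sequence))}


def alignment_map_from_rows(query_row: str, template_row: str) -> dict[int, int]:
    """Query position -> template position from two rows of one alignment.

    Both rows must have equal (gapped) length; positions where either row is
    gapped are unmapped.
    """
    if len(query_row) != len(template_row):
        raise GcouplerError("aligned rows differ in length")
    mapping: dict[int, int] = {}
    qi = ti = 0
    for qc, tc in zip(query_row, template_row):
        q_gap, t_gap = qc in "-.", tc in "-."
        if not q_gap and not t_gap:
            mapping[qi] = ti
        if not q_gap:
            qi += 1
        if not t_gap:
            ti += 1
    return mapping


def alignment_map_from_fasta(path, query_id: str, template_id: str) -> dict[int, int]:
    """Query -> template position mapping read from an aligned FASTA file."""
    from .hmm import read_alignment_fasta

    ids, rows = read_alignment_fasta(path)
    try:
        q = rows[ids.index(query_id)]
        t = rows[ids.index(template_id)]
    except ValueError as err:
        raise GcouplerError(f"identifier missing from {path}: {err}") from None
    return alignment_map_from_rows(q, t)


def _template_residues(
    sequence: str, mapping: Mapping[int, int]
) -> dict[int, str]:
    """Invert a query->template mapping into template position -> residue."""
    out: dict[int, str] = {}
    for q, t in mapping.items():
        if not 0 <= q < len(sequence):
            raise GcouplerError(f"alignment maps position {q} outside the sequence")
        out[t] = sequence[q].upper()
    return out


def _score_from_maps(
    template: TemplateComplex,
    rec_res: Mapping[int, str],
    gal_res: Mapping[int, str],
) -> tuple[float, int]:
    raw, skipped = 0.0, 0
    for rp, gp in template.contacts:
        ra = rec_res.get(rp)
        ga = gal_res.get(gp)
        if ra is None or ga is None or ra not in AA_INDEX or ga not in AA_INDEX:
            skipped += 1
            continue
        raw += template.potential[AA_INDEX[ra], AA_INDEX[ga]]
    return raw, skipped


def score_complex(
    template: TemplateComplex,
    receptor: str,
    galpha: str,
    receptor_map: Mapping[int, int] | None = None,
    galpha_map: Mapping[int, int] | None = None,
) -> tuple[float, int]:
    """Raw potential sum over the template contacts: (score, skipped contacts).

    ``*_map`` align query positions to template positions; by default the
    query is assumed to lie in template coordinates already.  Contacts whose
    receptor or Gα side is unaligned (or gapped/non-standard) are skipped.
    """
    if receptor_map is None:
        receptor_map = identity_alignment(receptor)
    if galpha_map is None:
        galpha_map = identity_alignment(galpha)
    rec_res = _template_residues(receptor, receptor_map)
    gal_res = _template_residues(galpha, galpha_map)
    if not rec_res or not gal_res:
        raise GcouplerError("sequence does not map to the template chains")
    return _score_from_maps(template, rec_res, gal_res)


def permutation_zscore(
    template: TemplateComplex,
    receptor: str,
    galpha: str,
    receptor_map: Mapping[int, int] | None = None,
    galpha_map: Mapping[int, int] | None = None,
    n_perm: int = 100,
    seed: int = 0,
    permute_side: str = "receptor",
) -> StructScore:
    """Permutation Z-score of the raw interface score.

    By default the null shuffles the receptor's aligned residues over its
    aligned template positions, holding the Gα side fixed (chimeras differ
    only in a short tail); ``permute_side="galpha"`` shuffles the other
    chain instead.  z = (raw - mean) / max(sd, SD_FLOOR); the p-value uses
    the add-one estimator p = (1 + #{null >= raw}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise GcouplerError("n_perm must be >= 1")
    if permute_side not in ("receptor", "galpha"):
        raise GcouplerError("permute_side must be 'receptor' or 'galpha'")
    if receptor_map is None:
        receptor_map = identity_alignment(receptor)
    if galpha_map is None:
        galpha_map = identity_alignment(galpha)
    rec_res = _template_residues(receptor, receptor_map)
    gal_res = _template_residues(galpha, galpha_map)
    raw, _ = _score_from_maps(template, rec_res, gal_res)

    rng = np.random.default_rng(seed)
    target = rec_res if permute_side == "receptor" else gal_res
    positions = list(target)
    residues = [target[p] for p in positions]
    null = np.empty(n_perm)
    for k in range(n_perm):
        perm = rng.permutation(len(residues))
        shuffled = {positions[i]: residues[perm[i]] for i in range(len(positions))}
        if permute_side == "receptor":
            null[k], _ = _score_from_maps(template, shuffled, gal_res)
        else:
            null[k], _ = _score_from_maps(template, rec_res, shuffled)
    sd = float(null.std())
    z = 0.0 if sd < SD_FLOOR else float((raw - null.mean()) / sd)
    p = float((1 + int(np.sum(null >= raw - 1e-12))) / (n_perm + 1))
    return StructScore(raw=float(raw), z=z, p=p, n_perm=n_perm)


def template_suitability(
    z_coupled: Sequence[float],
    z_uncoupled: Sequence[float],
    alpha: float = 0.05,
) -> bool:
    """Is a template informative for a Gα?  Two-sided rank-sum p < alpha."""
    if len(z_coupled) < 3 or len(z_uncoupled) < 3:
        warnings.warn("fewer than 3 scores in a group; template marked unsuitable")
        return False
    stat = stats.ranksums(z_coupled, z_uncoupled)
    return bool(stat.pvalue < alpha)


def extract_contacts(
    path: str | Path,
    receptor_chain: str,
    galpha_chain: str,
    cutoff: float = 5.0,
) -> list[tuple[int, int]]:
    """Interface contacts from a PDB file: residue pairs with any heavy-atom
    pair within ``cutoff`` Å, as 0-based residue indices per chain."""
    import gemmi

    structure = gemmi.read_structure(str(path))
    model = structure[0]
    chains = {ch.name: ch for ch in model}
    for name in (receptor_chain, galpha_chain):
        if name not in chains:
            raise GcouplerError(f"chain {name!r} missing from {path}")

    def heavy_coords(chain):
        out = []
        for res in chain:
            atoms = [a.pos for a in res if a.element.name != "H"]
            out.append(atoms)
        return out

    rec = heavy_coords(chains[receptor_chain])
    gal = heavy_coords(chains[galpha_chain])
    contacts = []
    for i, ra in enumerate(rec):
        for j, ga in enumerate(gal):
            found = False
            for a in ra:
                for b in ga:
                    if a.dist(b) <= cutoff:
                        found = True
                        break
                if found:
                    break
            if found:
                contacts.append((i, j))
    return contacts


def read_potential_tsv(path: str | Path) -> np.ndarray:
    """20x20 potential table from TSV (row/column index = amino acids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df = df.loc[list(AMINO_ACIDS), list(AMINO_ACIDS)]
    return df.to_numpy(dtype=float)


def write_potential_tsv(potential: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(potential, index=list(AMINO_ACIDS), columns=list(AMINO_ACIDS)).to_csv(
        path, sep="\t"
    )
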