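"""Minimal profile hidden Markov models for 7TM family alignments.

A profile is built from a gapped alignment: columns whose non-gap fraction is
>= ``symfrac`` (inclusive, default 0.5) become match ("consensus") columns;
per-column emission probabilities and match/insert/delete transition
probabilities are estimated with Laplace pseudocounts.  Queries are aligned by
Viterbi decoding in log-odds (bit) space against a uniform background;
insert states emit the background, so only match emissions and transitions
contribute to the score.  The architecture is a reduced plan7: one
match/insert/delete node per consensus column, all nine inter-state
transitions allowed, glocal decoding (the whole profile is traversed, the
whole query is consumed).

Position "bit-scores" — log2(emission / background) — are the per-residue
conservation scores downstream feature extraction consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .constants import (
    AA_INDEX,
    AMBIGUOUS_AA,
    AMINO_ACIDS,
    DEFAULT_PSEUDOCOUNT,
    DEFAULT_SYMFRAC,
    GAP_CHARS,
    N_AA,
)
from .errors import GcouplerError, NoMatchError

_TRANSITION_KEYS = ("mm", "mi", "md", "im", "ii", "id", "dm", "di", "dd")
_NEG_INF = -np.inf

#: Predecessor-state preference on Viterbi ties: match > delete > insert.
_STATE_ORDER = ("m", "d", "i")


@dataclass
class ProfileHMM:
    """Match-state profile model over the 20-letter amino-acid alphabet."""

    consensus_columns: np.ndarray  # original alignment column indices, len L
    emissions: np.ndarray  # (L, 20) match emission probabilities
    background: np.ndarray  # (20,)
    transitions: dict[str, np.ndarray]  # each (L+1,), node 0 = begin
    symfrac: float = DEFAULT_SYMFRAC
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    _col_index: dict[int, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.consensus_columns = np.asarray(self.consensus_columns, dtype=int)
        if np.any(np.diff(self.consensus_columns) <= 0):
            raise ValueError("consensus columns must be strictly increasing")
        if not np.allclose(self.emissions.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("emission rows must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")
        self._col_index = {int(c): i for i, c in enumerate(self.consensus_columns)}

    @property
    def n_columns(self) -> int:
        return len(self.consensus_columns)

    def is_consensus(self, original_column: int) -> bool:
        return int(original_column) in self._col_index

    def column_index(self, original_column: int) -> int:
        """Consensus index (0-based node - 1) of an original alignment column."""
        try:
            return self._col_index[int(original_column)]
        except KeyError:
            raise GcouplerError(
                f"column {original_column} is not a consensus column of this profile"
            ) from None

    # -- bit-scores ------------------------------------------------------

    def bitscore(self, original_column: int, residue: str) -> float:
        """log2(emission / background) of ``residue`` at a consensus column."""
        i = self.column_index(original_column)
        residue = residue.upper()
        if residue in AMBIGUOUS_AA:
            return 0.0  # unknown residues emit the background
        a = AA_INDEX[residue]
        return float(np.log2(self.emissions[i, a] / self.background[a]))

    def bitscore_row(self, original_column: int) -> np.ndarray:
        """All 20 residue bit-scores at a consensus column."""
        i = self.column_index(original_column)
        return np.log2(self.emissions[i] / self.background)

    def min_bitscore(self, original_column: int) -> float:
        """Least-favoured (minimum) residue bit-score at a column.

        Used as the sentinel value when a query has no residue at a selected
        position: the least-conserved score the column can produce.
        """
        return float(self.bitscore_row(original_column).min())

    def consensus_sequence(self) -> str:
        """Most probable residue per column (ties broken alphabetically)."""
        return "".join(AMINO_ACIDS[int(np.argmax(row))] for row in self.emissions)

    # -- serialization ---------------------------------------------------

    def serialize(self) -> str:
        """Canonical TSV text (12 significant digits; round-trip stable)."""
        lines = [
            f"#symfrac\t{self.symfrac}",
            f"#pseudocount\t{self.pseudocount}",
            "#background\t" + "\t".join(f"{b:.12g}" for b in self.background),
            "\t".join(["node", "column"] + list(AMINO_ACIDS) + list(_TRANSITION_KEYS)),
        ]
        for j in range(self.n_columns + 1):
            emis = ["" if j == 0 else f"{e:.12g}" for e in
                    (self.emissions[j - 1] if j > 0 else np.zeros(N_AA))]
            trans = [f"{self.transitions[k][j]:.12g}" for k in _TRANSITION_KEYS]
            col = -1 if j == 0 else int(self.consensus_columns[j - 1])
            lines.append("\t".join([str(j), str(col)] + emis + trans))
        return "\n".join(lines) + "\n"

    def to_tsv(self, path: str | Path) -> None:
        Path(path).write_text(self.serialize())

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ProfileHMM":
        symfrac, pseudocount, background = DEFAULT_SYMFRAC, DEFAULT_PSEUDOCOUNT, None
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#symfrac"):
                    symfrac = float(line.split("\t")[1])
                elif line.startswith("#pseudocount"):
                    pseudocount = float(line.split("\t")[1])
                elif line.startswith("#background"):
                    background = np.array([float(x) for x in line.split("\t")[1:]])
                elif line.startswith("node\t") or not line:
                    continue
                else:
                    rows.append(line.split("\t"))
        if background is None:
            raise GcouplerError(f"malformed profile file: {path}")
        n_nodes = len(rows)
        L = n_nodes - 1
        columns = np.zeros(L, dtype=int)
        emissions = np.zeros((L, N_AA))
        transitions = {k: np.zeros(n_nodes) for k in _TRANSITION_KEYS}
        for row in rows:
            j = int(row[0])
            if j > 0:
                columns[j - 1] = int(row[1])
                emissions[j - 1] = [float(x) for x in row[2 : 2 + N_AA]]
            for ki, k in enumerate(_TRANSITION_KEYS):
                transitions[k][j] = float(row[2 + N_AA + ki])
        return cls(columns, emissions, background, transitions, symfrac, pseudocount)


@dataclass
class ProfileAlignment:
    """Viterbi alignment of one query to a profile.

    ``column_of_residue`` maps query residue index -> consensus index (both
    0-based); ``insertions`` are (after-consensus-index, start, end) runs of
    unmapped query residues (after = -1 for N-terminal overhangs);
    ``deletions`` are consensus indices with no query residue.
    """

    query: str
    score: float
    column_of_residue: dict[int, int]
    insertions: list[tuple[int, int, int]]
    deletions: list[int]

    def residue_at(self, consensus_index: int) -> str | None:
        for qi, ci in self.column_of_residue.items():
            if ci == consensus_index:
                return self.query[qi]
        return None

    def residue_map(self) -> dict[int, str]:
        """Consensus index -> aligned query residue."""
        return {ci: self.query[qi] for qi, ci in self.column_of_residue.items()}

    def insert_residues(self) -> dict[int, list[int]]:
        """After-consensus-index -> query residue indices inserted there."""
        out: dict[int, list[int]] = {}
        for after, start, end in self.insertions:
            out.setdefault(after, []).extend(range(start, end))
        return out


def sanitize(sequence: str) -> str:
    """Upper-case and validate a protein sequence; ambiguity codes become X."""
    seq = sequence.upper().replace("*", "")
    cleaned = []
    for ch in seq:
        if ch in AA_INDEX:
            cleaned.append(ch)
        elif ch in AMBIGUOUS_AA:
            cleaned.append("X")
        elif ch in GAP_CHARS:
            continue
        else:
            raise GcouplerError(f"illegal character in sequence: {ch!r}")
    if not cleaned:
        raise GcouplerError("empty sequence after sanitation")
    return "".join(cleaned)


def consensus_mask(rows: Sequence[str], symfrac: float = DEFAULT_SYMFRAC) -> np.ndarray:
    """Boolean mask of consensus columns (non-gap fraction >= symfrac)."""
    arr = np.array([list(r) for r in rows])
    nongap = ~np.isin(arr, list(GAP_CHARS))
    frac = nongap.mean(axis=0)
    return frac >= symfrac


def _state_events(row: str, mask: np.ndarray) -> list[tuple[str, int]]:
    """Plan7 state path of one aligned row: [(state, node), ...], begin at node 0."""
    events: list[tuple[str, int]] = [("m", 0)]  # begin treated as M_0
    node = 0
    for col, ch in enumerate(row):
        is_gap = ch in GAP_CHARS
        if mask[col]:
            node += 1
            events.append(("d" if is_gap else "m", node))
        elif not is_gap:
            events.append(("i", node))
    return events


def build_profile(
    rows: Sequence[str],
    symfrac: float = DEFAULT_SYMFRAC,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    background: np.ndarray | None = None,
) -> ProfileHMM:
    """Estimate a ProfileHMM from gapped, equal-length alignment rows."""
    if not rows:
        raise GcouplerError("empty alignment")
    rows = [r.upper() for r in rows]
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise GcouplerError("alignment rows must have uniform length")
    mask = consensus_mask(rows, symfrac)
    columns = np.flatnonzero(mask)
    L = len(columns)
    if L == 0:
        raise GcouplerError("no column meets the consensus rule")
    if background is None:
        background = np.full(N_AA, 1.0 / N_AA)

    counts = np.zeros((L, N_AA))
    for r in rows:
        for i, col in enumerate(columns):
            ch = r[col]
            if ch in AA_INDEX:
                counts[i, AA_INDEX[ch]] += 1
    emissions = (counts + pseudocount) / (
        counts.sum(axis=1, keepdims=True) + N_AA * pseudocount
    )

    tcounts = {k: np.zeros(L + 1) for k in _TRANSITION_KEYS}
    for r in rows:
        events = _state_events(r, mask)
        for (s1, j1), (s2, _) in zip(events, events[1:]):
            tcounts[s1 + s2][j1] += 1
        # transition of the final state to the end node, counted as "-> match"
        s_last, j_last = events[-1]
        tcounts[s_last + "m"][j_last] += 1
    transitions = {}
    for src in "mid":
        block = np.stack([tcounts[src + dst] for dst in "mid"])  # (3, L+1)
        block = block + pseudocount
        block = block / block.sum(axis=0, keepdims=True)
        for bi, dst in enumerate("mid"):
            transitions[src + dst] = block[bi]
    return ProfileHMM(columns, emissions, np.asarray(background, float), transitions,
                      symfrac, pseudocount)


def _emission_bits(hmm: ProfileHMM, query: str) -> np.ndarray:
    """(n, L) match emission bit-scores per query residue and node."""
    bits = np.zeros((len(query), hmm.n_columns))
    logodds = np.log2(hmm.emissions / hmm.background)  # (L, 20)
    for qi, ch in enumerate(query):
        if ch in AA_INDEX:
            bits[qi] = logodds[:, AA_INDEX[ch]]
        # unknown 'X': background emission, 0 bits
    return bits


def align_to_profile(
    query: str,
    hmm: ProfileHMM,
    score_floor: float | None = 0.0,
) -> ProfileAlignment:
    """Glocal Viterbi alignment of a query sequence to the profile.

    All consensus nodes are traversed (via match or delete) and every query
    residue is either matched or inserted.  Ties prefer match > delete >
    insert, which makes the decoded path deterministic.  If a ``score_floor``
    is given and the alignment scores below it (in bits), a
    :class:`NoMatchError` signals a sequence unrelated to the family.
    """
    query = sanitize(query)
    L, n = hmm.n_columns, len(query)
    tsc = {k: np.log2(hmm.transitions[k]) for k in _TRANSITION_KEYS}
    esc = _emission_bits(hmm, query)

    vm = np.full((L + 1, n + 1), _NEG_INF)
    vi = np.full((L + 1, n + 1), _NEG_INF)
    vd = np.full((L + 1, n + 1), _NEG_INF)
    # predecessor state pointers: 0=m, 1=d, 2=i, -1=none
    pm = np.full((L + 1, n + 1), -1, dtype=np.int8)
    pi = np.full((L + 1, n + 1), -1, dtype=np.int8)
    pd_ = np.full((L + 1, n + 1), -1, dtype=np.int8)

    vm[0, 0] = 0.0

    def best(m_val: float, d_val: float, i_val: float) -> tuple[float, int]:
        # tie-break: match > delete > insert
        vals = (m_val, d_val, i_val)
        bi = 0
        for k in (1, 2):
            if vals[k] > vals[bi]:
                bi = k
        return vals[bi], (0, 1, 2)[bi]

    for j in range(0, L + 1):
        if j > 0:
            # delete: no residue consumed, vectorized over i
            cand = np.stack([
                vm[j - 1] + tsc["md"][j - 1],
                vd[j - 1] + tsc["dd"][j - 1],
                vi[j - 1] + tsc["id"][j - 1],
            ])  # order m, d, i; argmax takes the first max => match > delete > insert
            idx = np.argmax(cand, axis=0)
            vd[j] = cand[idx, np.arange(n + 1)]
            pd_[j] = idx.astype(np.int8)
            pd_[j, vd[j] == _NEG_INF] = -1
            # match: consumes one residue
            for i in range(1, n + 1):
                val, src = best(
                    vm[j - 1, i - 1] + tsc["mm"][j - 1],
                    vd[j - 1, i - 1] + tsc["dm"][j - 1],
                    vi[j - 1, i - 1] + tsc["im"][j - 1],
                )
                vm[j, i] = val + esc[i - 1, j - 1]
                pm[j, i] = src if np.isfinite(val) else -1
        # insert at node j: consumes residues, sequential in i
        for i in range(1, n + 1):
            val, src = best(
                vm[j, i - 1] + tsc["mi"][j],
                vd[j, i - 1] + tsc["di"][j],
                vi[j, i - 1] + tsc["ii"][j],
            )
            if np.isfinite(val):
                vi[j, i] = val
                pi[j, i] = src

    end_val, end_state = best(
        vm[L, n] + tsc["mm"][L],
        vd[L, n] + tsc["dm"][L],
        vi[L, n] + tsc["im"][L],
    )
    if not np.isfinite(end_val):
        raise NoMatchError("no admissible alignment path")
    if score_floor is not None and end_val < score_floor:
        raise NoMatchError(
            f"alignment score {end_val:.2f} bits below reporting floor {score_floor}"
        )

    # traceback
    column_of_residue: dict[int, int] = {}
    insert_runs: dict[int, list[int]] = {}
    deletions: list[int] = []
    state, j, i = ("m", "d", "i")[end_state], L, n
    while not (state == "m" and j == 0):
        if state == "m":
            column_of_residue[i - 1] = j - 1
            prev = pm[j, i]
            j, i = j - 1, i - 1
        elif state == "d":
            deletions.append(j - 1)
            prev = pd_[j, i]
            j = j - 1
        else:  # insert
            insert_runs.setdefault(j - 1, []).append(i - 1)
            prev = pi[j, i]
            i = i - 1
        state = ("m", "d", "i")[prev]
    insertions = []
    for after, idxs in sorted(insert_runs.items()):
        idxs = sorted(idxs)
        start = idxs[0]
        for a, b in zip(idxs, idxs[1:] + [None]):
            if b is None or b != a + 1:
                insertions.append((after, start, a + 1))
                start = b
    deletions.sort()
    return ProfileAlignment(query, float(end_val), column_of_residue, insertions, deletions)


def read_hmmer3(path: str | Path, background: np.ndarray | None = None) -> ProfileHMM:
    """Read the match states of a HMMER3 text profile (e.g. a seed 7TM model).

    Parses the ``HMM`` alphabet header and the per-node match-emission lines
    (values are negative natural logs of probabilities; ``*`` means zero).
    Insert emissions and the original transition lines are not preserved:
    transitions are set to a generic profile prior (match-favouring), since
    only match emissions/bit-scores are needed from an external seed model.
    Consensus columns are taken from the MAP annotation when present.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    alphabet: list[str] = []
    map_on = False
    emissions: list[list[float]] = []
    columns: list[int] = []
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if parts[:1] == ["HMM"]:
            alphabet = parts[1:]
            break
        if parts[:1] == ["MAP"]:
            map_on = parts[1].lower() == "yes"
        i += 1
    if not alphabet:
        raise GcouplerError(f"not a HMMER3 text profile: {path}")
    i += 2  # skip the transition-name header line
    node = 0
    while i < len(lines):
        parts = lines[i].split()
        if parts and parts[0] == "//":
            break
        if parts and parts[0] == str(node + 1):
            node += 1
            values = [0.0 if v == "*" else np.exp(-float(v))
                      for v in parts[1 : 1 + len(alphabet)]]
            row = np.zeros(N_AA)
            for aa, v in zip(alphabet, values):
                if aa in AA_INDEX:
                    row[AA_INDEX[aa]] = v
            row = row / row.sum()
            emissions.append(list(row))
            extras = parts[1 + len(alphabet):]
            if map_on and extras:
                columns.append(int(extras[0]) - 1)  # MAP is 1-based
            else:
                columns.append(node - 1)
            i += 3  # skip the insert-emission and transition lines
        else:
            i += 1
    if not emissions:
        raise GcouplerError(f"no match states found in {path}")
    L = len(emissions)
    if background is None:
        background = np.full(N_AA, 1.0 / N_AA)
    # generic match-favouring prior in place of the file's transitions
    transitions = {}
    for src in "mid":
        probs = {"m": 0.9, "i": 0.05, "d": 0.05}
        for dst in "mid":
            transitions[src + dst] = np.full(L + 1, probs[dst])
    return ProfileHMM(np.asarray(columns), np.asarray(emissions),
                      np.asarray(background, float), transitions)


def read_alignment_fasta(path: str | Path) -> tuple[list[str], list[str]]:
    """Read an aligned FASTA file -> (ids, gapped rows)."""
    ids, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(str(rec.seq).upper())
    if not rows:
        raise GcouplerError(f"no sequences in {path}")
    return ids, rows


def write_alignment_fasta(ids: Iterable[str], rows: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, row in zip(ids, rows):
            fh.write(f">{name}\n{row}\n")
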