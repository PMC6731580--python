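"""Protein sequence retrieval, global alignment and percent-identity matrices.

This is the local stand-in for the EBI dbfetch + Clustal Omega services the
recommender relies on: sequences come from a FASTA collection (or, when
enabled, the remote dbfetch contract); similarity is the percent identity of
an optimal global (Needleman–Wunsch) pairwise alignment, counted over columns
where both sequences have a residue — close enough to the Clustal convention
for ranking purposes.  Remote mode can instead parse the percent-identity
matrix text a Clustal-style service emits.

Default scoring is match +1 / mismatch 0 / gap −1 with linear gaps: the
requirement here is a stable ranking signal, not biology-grade alignment.
A substitution table (e.g. BLOSUM62 from Biopython) can be passed for
realistic proteins.
"""

from __future__ import annotations

import re
import urllib.request
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from Bio import SeqIO

from .errors import InvalidInputError, NotFoundError, RemoteServiceError

AMINO_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class ProteinRecord:
    accession: str
    sequence: str

    def __post_init__(self):
        if not self.accession:
            raise InvalidInputError("protein record needs an accession")
        seq = self.sequence.upper()
        if not seq:
            raise InvalidInputError(f"{self.accession}: empty sequence")
        bad = set(seq) - AMINO_ALPHABET
        if bad:
            raise InvalidInputError(
                f"{self.accession}: non-amino-acid letters {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", seq)


@dataclass(frozen=True)
class Scoring:
    match: float = 1.0
    mismatch: float = 0.0
    gap: float = -1.0
    #: optional substitution table {(a, b): score}; overrides match/mismatch
    table: Optional[Mapping[tuple[str, str], float]] = None

    def pair(self, a: str, b: str) -> float:
        if self.table is not None:
            return self.table.get((a, b), self.table.get((b, a)))
        return self.match if a == b else self.mismatch


DEFAULT_SCORING = Scoring()


@dataclass(frozen=True)
class Alignment:
    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self):
        if len(self.aligned_a) != len(self.aligned_b):
            raise InvalidInputError("aligned strings must have equal length")

    @property
    def columns(self) -> int:
        return len(self.aligned_a)


def global_align(a: str, b: str, scoring: Scoring = DEFAULT_SCORING) -> Alignment:
    """Optimal global alignment by Needleman–Wunsch dynamic programming.

    Traceback tie-break is deterministic: diagonal, then up (gap in ``b``),
    then left (gap in ``a``).
    """
    if not a or not b:
        raise InvalidInputError("cannot align an empty sequence")
    n, m = len(a), len(b)
    gap = scoring.gap
    score = np.empty((n + 1, m + 1), dtype=float)
    score[0, :] = gap * np.arange(m + 1)
    score[:, 0] = gap * np.arange(n + 1)
    for i in range(1, n + 1):
        ai = a[i - 1]
        row = score[i - 1]
        for j in range(1, m + 1):
            score[i, j] = max(
                row[j - 1] + scoring.pair(ai, b[j - 1]),
                row[j] + gap,
                score[i, j - 1] + gap,
            )
    # deterministic traceback
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and score[i, j] == score[i - 1, j - 1] + scoring.pair(
            a[i - 1], b[j - 1]
        ):
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i, j = i - 1, j - 1
        elif i > 0 and score[i, j] == score[i - 1, j] + gap:
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
    return Alignment("".join(reversed(out_a)), "".join(reversed(out_b)),
                     float(score[n, m]))


def percent_identity(alignment: Alignment) -> float:
    """100 × identical columns / columns where both sequences have a residue,
    rounded half-up to two decimals."""
    both = ident = 0
    for x, y in zip(alignment.aligned_a, alignment.aligned_b):
        if x != "-" and y != "-":
            both += 1
            if x == y:
                ident += 1
    if both == 0:
        raise InvalidInputError("alignment has no columns with residues in both rows")
    value = Decimal(100 * ident) / Decimal(both)
    return float(value.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class SimilarityMatrix:
    accessions: tuple[str, ...]
    values: tuple[tuple[float, ...], ...]

    def __post_init__(self):
        k = len(self.accessions)
        if any(len(row) != k for row in self.values) or len(self.values) != k:
            raise InvalidInputError("similarity matrix must be square")

    def get(self, acc_a: str, acc_b: str) -> float:
        ia = self.accessions.index(acc_a)
        ib = self.accessions.index(acc_b)
        return self.values[ia][ib]

    def row(self, accession: str) -> dict[str, float]:
        i = self.accessions.index(accession)
        return dict(zip(self.accessions, self.values[i]))

    def as_array(self) -> np.ndarray:
        return np.array(self.values)


def similarity_matrix(
    records: Sequence[ProteinRecord], scoring: Scoring = DEFAULT_SCORING
) -> SimilarityMatrix:
    """Symmetric pairwise percent-identity matrix (diagonal 100.00).

    Values follow their accessions: reordering the records permutes rows and
    columns but never changes any pairwise value.
    """
    if len(records) < 2:
        raise InvalidInputError("similarity matrix needs at least two records")
    accs = [r.accession for r in records]
    if len(set(accs)) != len(accs):
        raise InvalidInputError("duplicate accessions in similarity matrix input")
    k = len(records)
    vals = [[100.0] * k for _ in range(k)]
    for i in range(k):
        for j in range(i + 1, k):
            pid = percent_identity(
                global_align(records[i].sequence, records[j].sequence, scoring)
            )
            vals[i][j] = vals[j][i] = pid
    return SimilarityMatrix(tuple(accs), tuple(tuple(row) for row in vals))


# --------------------------------------------------------------------------
# sequence sources

def read_fasta(path: str | Path) -> dict[str, ProteinRecord]:
    records: dict[str, ProteinRecord] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        acc = rec.id.split("|")[1] if rec.id.count("|") >= 2 else rec.id
        records[acc] = ProteinRecord(accession=acc, sequence=str(rec.seq))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in sorted(records, key=lambda r: r.accession):
            fh.write(f">{rec.accession}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


class SequenceSource:
    """Accession → sequence lookup: local FASTA first, remote dbfetch on miss.

    Remote lookup is off by default; ``fetch_calls`` counts actual reads from
    either backing store so the cache contract is testable.
    """

    DBFETCH_URL = "https://www.ebi.ac.uk/Tools/dbfetch/dbfetch"

    def __init__(
        self,
        fasta_path: Optional[str | Path] = None,
        records: Optional[Mapping[str, ProteinRecord]] = None,
        remote_enabled: bool = False,
        remote_url: Optional[str] = None,
        timeout: float = 30.0,
    ):
        self._local: dict[str, ProteinRecord] = dict(records or {})
        self._fasta_path = Path(fasta_path) if fasta_path else None
        self._fasta_loaded = False
        self._cache: dict[str, ProteinRecord] = {}
        self.remote_enabled = remote_enabled
        self.remote_url = remote_url or self.DBFETCH_URL
        self.timeout = timeout
        self.fetch_calls = 0

    def _load_fasta(self) -> None:
        if self._fasta_path and not self._fasta_loaded:
            self._local.update(read_fasta(self._fasta_path))
            self._fasta_loaded = True

    def fetch(self, accession: str) -> ProteinRecord:
        if accession in self._cache:
            return self._cache[accession]
        self._load_fasta()
        self.fetch_calls += 1
        if accession in self._local:
            rec = self._local[accession]
        elif self.remote_enabled:
            rec = self._fetch_remote(accession)
        else:
            raise NotFoundError(f"unknown protein accession: {accession}")
        self._cache[accession] = rec
        return rec

    def _fetch_remote(self, accession: str) -> ProteinRecord:
        url = (
            f"{self.remote_url}?db=uniprotkb&id={accession}"
            "&format=fasta&style=raw"
        )
        try:
            with urllib.request.urlopen(url, timeout=self.timeout) as resp:
                text = resp.read().decode()
        except Exception as exc:
            raise RemoteServiceError(f"dbfetch failed for {accession}: {exc}") from exc
        lines = [l.strip() for l in text.splitlines() if l and not l.startswith(">")]
        if not lines:
            raise NotFoundError(f"dbfetch returned no sequence for {accession}")
        return ProteinRecord(accession=accession, sequence="".join(lines))


# --------------------------------------------------------------------------
# Clustal-style percent-identity matrix text

_PIM_ROW = re.compile(r"^\s*\d+:\s+(\S+)((?:\s+\d+(?:\.\d+)?)+)\s*$")


def parse_percent_identity_matrix(text: str) -> SimilarityMatrix:
    """Parse the percent-identity matrix text format emitted by Clustal-style
    multiple-alignment services (``  1: P26433  100.00  89.49 ...``)."""
    accs: list[str] = []
    rows: list[list[float]] = []
    for line in text.splitlines():
        m = _PIM_ROW.match(line)
        if not m:
            continue
        accs.append(m.group(1))
        rows.append([float(x) for x in m.group(2).split()])
    if not accs:
        raise InvalidInputError("no matrix rows found in percent-identity text")
    return SimilarityMatrix(tuple(accs), tuple(tuple(r) for r in rows))
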