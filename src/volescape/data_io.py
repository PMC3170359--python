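"""Core data containers and file I/O.

The pipeline revolves around three containers:

* :class:`GenotypeTable` — diploid multilocus genotypes with population,
  sex and planar-coordinate metadata (the hub of every nuclear analysis);
* :class:`HaplotypeAlignment` — an aligned set of mitochondrial sequences
  with population labels;
* :class:`SymmetricMatrix` — a labelled pairwise matrix, the common currency
  of every distance-based stage (genetic, Euclidean, least-cost).

File formats supported: GENEPOP (2- and 3-digit allele dialects), FASTA
alignments, and a plain CSV metadata table
(``sample_id,population,sex,easting,northing``).
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeTable",
    "HaplotypeAlignment",
    "SymmetricMatrix",
    "GenepopFormatError",
    "parse_genepop",
    "write_genepop",
    "parse_fasta_alignment",
    "attach_sample_metadata",
]

MISSING = 0  # allele code for a missing gene

SEX_CODES = ("male", "female", "unknown")


class GenepopFormatError(ValueError):
    """Raised when a GENEPOP file violates the format."""


@dataclass
class GenotypeTable:
    """Diploid multilocus genotypes plus per-sample metadata.

    ``calls`` is an ``(n_samples, n_loci, 2)`` integer array of allele codes;
    a missing call is stored as ``(0, 0)``.  A call is either a full diploid
    pair of positive codes or wholly missing — partially missing calls are
    not representable by construction.
    """

    sample_id: list[str]
    population: np.ndarray          # dtype object/str, shape (n,)
    calls: np.ndarray               # int, shape (n, L, 2)
    locus_names: list[str]
    sex: np.ndarray | None = None   # "male"/"female"/"unknown", shape (n,)
    coords: np.ndarray | None = None  # float meters, shape (n, 2), NaN if absent

    def __post_init__(self) -> None:
        self.population = np.asarray(self.population, dtype=object)
        self.calls = np.asarray(self.calls, dtype=np.int64)
        n, L = len(self.sample_id), len(self.locus_names)
        if self.calls.shape != (n, L, 2):
            raise ValueError(f"calls shape {self.calls.shape} != ({n}, {L}, 2)")
        if np.any(self.calls < 0):
            raise ValueError("allele codes must be positive (0 = missing)")
        half = (self.calls == MISSING).sum(axis=2) == 1
        if np.any(half):
            raise ValueError("a call must be a full pair or wholly missing")
        if self.sex is None:
            self.sex = np.asarray(["unknown"] * n, dtype=object)
        else:
            self.sex = np.asarray(self.sex, dtype=object)
            bad = set(self.sex) - set(SEX_CODES)
            if bad:
                raise ValueError(f"unknown sex codes: {bad}")
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
            if self.coords.shape != (n, 2):
                raise ValueError("coords must be (n, 2)")

    # -- basic interrogation -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_id)

    @property
    def n_loci(self) -> int:
        return len(self.locus_names)

    @property
    def populations(self) -> list[str]:
        """Population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.population:
            seen.setdefault(p, None)
        return list(seen)

    def missing_mask(self) -> np.ndarray:
        """Boolean (n, L): True where the call is missing."""
        return self.calls[:, :, 0] == MISSING

    def pop_indices(self, pop: str) -> np.ndarray:
        return np.flatnonzero(self.population == pop)

    def subset(self, idx: np.ndarray | list[int]) -> "GenotypeTable":
        idx = np.asarray(idx)
        return GenotypeTable(
            sample_id=[self.sample_id[i] for i in idx],
            population=self.population[idx],
            calls=self.calls[idx],
            locus_names=list(self.locus_names),
            sex=self.sex[idx],
            coords=None if self.coords is None else self.coords[idx],
        )

    def allele_counts(self, pop: str, locus: int) -> dict[int, int]:
        """Counts of each allele code among genotyped genes of ``pop`` at ``locus``."""
        sub = self.calls[self.pop_indices(pop), locus, :].ravel()
        sub = sub[sub != MISSING]
        vals, cnt = np.unique(sub, return_counts=True)
        return dict(zip(vals.tolist(), cnt.tolist()))


@dataclass
class HaplotypeAlignment:
    """Aligned sequences over {A,C,G,T,N,-} with a population label each."""

    ids: list[str]
    seqs: np.ndarray                 # dtype '<U1', shape (n, L)
    population: np.ndarray           # object, shape (n,)

    ALPHABET = frozenset("ACGTN-")

    def __post_init__(self) -> None:
        self.seqs = np.asarray(self.seqs)
        self.population = np.asarray(self.population, dtype=object)
        if self.seqs.ndim != 2:
            raise ValueError("seqs must be a 2-D character array")
        bad = set(np.unique(self.seqs)) - self.ALPHABET
        if bad:
            raise ValueError(f"illegal characters in alignment: {bad}")

    @property
    def n_seqs(self) -> int:
        return self.seqs.shape[0]

    @property
    def length(self) -> int:
        return self.seqs.shape[1]

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.population:
            seen.setdefault(p, None)
        return list(seen)

    def pop_indices(self, pop: str) -> np.ndarray:
        return np.flatnonzero(self.population == pop)


@dataclass
class SymmetricMatrix:
    """Labelled symmetric pairwise matrix with a units tag.

    NaN marks a pair flagged missing; the diagonal is zero for distances.
    """

    labels: list[str]
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.labels)
        if self.values.shape != (k, k):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(
            np.nan_to_num(self.values), np.nan_to_num(self.values.T), equal_nan=True
        ):
            raise ValueError("matrix is not symmetric")

    @classmethod
    def from_condensed(
        cls, labels: list[str], condensed: np.ndarray, units: str = "", diag: float = 0.0
    ) -> "SymmetricMatrix":
        k = len(labels)
        m = np.full((k, k), diag, dtype=float)
        iu = np.triu_indices(k, 1)
        m[iu] = condensed
        m[(iu[1], iu[0])] = condensed
        return cls(labels, m, units)

    def condensed(self) -> np.ndarray:
        """Upper-triangle values in row-major pair order."""
        iu = np.triu_indices(len(self.labels), 1)
        return self.values[iu]

    def pair(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_tsv(self) -> str:
        return self.to_frame().to_csv(sep="\t")


# ---------------------------------------------------------------------------
# GENEPOP
# ---------------------------------------------------------------------------

_POP_RE = re.compile(r"^\s*pop\s*$", re.IGNORECASE)


def _split_genepop_token(token: str, lineno: int) -> tuple[int, int]:
    if len(token) == 4:
        w = 2
    elif len(token) == 6:
        w = 3
    else:
        raise GenepopFormatError(
            f"line {lineno}: genotype token '{token}' is not 4 or 6 characters"
        )
    if not token.isdigit():
        raise GenepopFormatError(f"line {lineno}: genotype token '{token}' not numeric")
    a, b = int(token[:w]), int(token[w:])
    if a == 0 or b == 0:
        # partial missing collapses to wholly missing: downstream estimators
        # need full diploid calls
        return (MISSING, MISSING)
    return (a, b)


def parse_genepop(text: str) -> GenotypeTable:
    """Parse GENEPOP-format content into a :class:`GenotypeTable`.

    Both the 2-digit and 3-digit per-allele dialects are auto-detected from
    the token length.  Populations are labelled ``pop1``, ``pop2``, ... in
    file order.  Sample name is the text before the comma; duplicated names
    are disambiguated with a numeric suffix.
    """
    lines = text.replace("\r\n", "\n").replace("\r", "\n").split("\n")
    while lines and not lines[-1].strip():
        lines.pop()
    if len(lines) < 3:
        raise GenepopFormatError("file too short for title, loci and a Pop block")

    # locus names: either one per line, or comma-separated on one line
    i = 1
    locus_names: list[str] = []
    while i < len(lines) and not _POP_RE.match(lines[i]):
        chunk = lines[i].strip()
        if chunk:
            locus_names.extend(t.strip() for t in chunk.split(",") if t.strip())
        i += 1
    if i == len(lines):
        raise GenepopFormatError("no 'Pop' line found")
    if not locus_names:
        raise GenepopFormatError("no locus names before first 'Pop'")

    sample_id: list[str] = []
    pops: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    name_count: dict[str, int] = {}
    pop_no = 0
    in_pop = False
    pop_size = 0
    for lineno, raw in enumerate(lines[i:], start=i + 1):
        line = raw.strip()
        if not line:
            continue
        if _POP_RE.match(line):
            if in_pop and pop_size == 0:
                raise GenepopFormatError(f"line {lineno}: empty Pop block")
            pop_no += 1
            in_pop = True
            pop_size = 0
            continue
        if "," not in line:
            raise GenepopFormatError(f"line {lineno}: expected 'name , genotypes'")
        name, geno = line.split(",", 1)
        name = name.strip()
        name_count[name] = name_count.get(name, 0) + 1
        if name_count[name] > 1:
            name = f"{name}_{name_count[name]}"
        tokens = geno.split()
        if len(tokens) != len(locus_names):
            raise GenepopFormatError(
                f"line {lineno}: {len(tokens)} genotypes for {len(locus_names)} loci"
            )
        rows.append([_split_genepop_token(t, lineno) for t in tokens])
        sample_id.append(name)
        pops.append(f"pop{pop_no}")
        pop_size += 1
    if pop_no == 0:
        raise GenepopFormatError("no 'Pop' line found")
    if pop_size == 0:
        raise GenepopFormatError("trailing empty Pop block")

    calls = np.array(rows, dtype=np.int64)
    return GenotypeTable(sample_id, np.array(pops, dtype=object), calls, locus_names)


def write_genepop(table: GenotypeTable, title: str = "volescape export") -> str:
    """Serialize a table as GENEPOP text (3-digit dialect).

    Raises ``ValueError`` for allele codes ≥ 1000 (unrepresentable) or an
    empty population.
    """
    if table.n_samples == 0:
        raise ValueError("cannot write an empty table")
    if np.any(table.calls >= 1000):
        raise ValueError("allele code >= 1000 cannot be written in 3-digit dialect")
    out = io.StringIO()
    out.write(title + "\n")
    for name in table.locus_names:
        out.write(name + "\n")
    for pop in table.populations:
        out.write("Pop\n")
        for i in table.pop_indices(pop):
            toks = [
                f"{a:03d}{b:03d}" for a, b in table.calls[i]
            ]
            out.write(f"{table.sample_id[i]} , " + " ".join(toks) + "\n")
    return out.getvalue()


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def parse_fasta_alignment(text: str, pop_map: dict[str, str]) -> HaplotypeAlignment:
    """Parse an aligned FASTA into a :class:`HaplotypeAlignment`.

    ``pop_map`` assigns a population label to every record id (the first
    whitespace-delimited token of the header).  Lowercase bases are upcased.
    """
    ids: list[str] = []
    seqs: list[str] = []
    cur: list[str] | None = None
    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            ids.append(line[1:].split()[0])
            cur = []
            seqs.append("")
        else:
            if cur is None:
                raise ValueError("sequence data before first FASTA header")
            seqs[-1] += line.upper()
    if len(ids) < 2:
        raise ValueError("an alignment needs at least 2 records")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"ragged alignment: lengths {sorted(lengths)}")
    missing = [i for i in ids if i not in pop_map]
    if missing:
        raise ValueError(f"samples not in pop_map: {missing}")
    arr = np.array([list(s) for s in seqs])
    pops = np.array([pop_map[i] for i in ids], dtype=object)
    return HaplotypeAlignment(ids, arr, pops)


# ---------------------------------------------------------------------------
# metadata CSV
# ---------------------------------------------------------------------------

def attach_sample_metadata(
    table: GenotypeTable,
    metadata: pd.DataFrame | str,
    strict: bool = True,
) -> GenotypeTable:
    """Bind a metadata table onto a genotype table.

    ``metadata`` is a DataFrame or CSV text with columns ``sample_id``,
    ``population`` and optionally ``sex``, ``easting``, ``northing``.
    Coordinates are taken verbatim as projected planar meters.  Under
    ``strict`` every table sample must appear in the metadata.
    """
    if isinstance(metadata, str):
        metadata = pd.read_csv(io.StringIO(metadata))
    if metadata["sample_id"].duplicated().any():
        dups = metadata.loc[metadata["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample_id in metadata: {dups}")
    meta = metadata.set_index("sample_id")
    absent = [s for s in table.sample_id if s not in meta.index]
    if absent and strict:
        raise ValueError(f"samples missing from metadata: {absent}")

    pops = np.array(table.population, dtype=object)
    sex = np.array(table.sex, dtype=object)
    coords = np.full((table.n_samples, 2), np.nan)
    if table.coords is not None:
        coords[:] = table.coords
    for i, s in enumerate(table.sample_id):
        if s not in meta.index:
            continue
        row = meta.loc[s]
        if "population" in meta.columns and not pd.isna(row["population"]):
            pops[i] = str(row["population"])
        if "sex" in meta.columns and not pd.isna(row.get("sex", np.nan)):
            v = str(row["sex"]).lower()
            sex[i] = v if v in SEX_CODES else "unknown"
        if "easting" in meta.columns and "northing" in meta.columns:
            coords[i] = (row["easting"], row["northing"])
    if np.all(np.isnan(coords)):
        coords_out = None
    else:
        coords_out = coords
    return replace(table, population=pops, sex=sex, coords=coords_out)
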