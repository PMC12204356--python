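"""A3M I/O, per-residue alignment-depth profiling, and domain-based MSA construction.

Domain-based MSA construction rebuilds a full-length alignment for a
multi-domain target from per-domain alignments: rows sharing a sequence
identifier across two or more domain MSAs are paired into one full-length row;
rows found in a single domain MSA are gap-padded outside their domain. The
combined alignment stacks three blocks — the full-length MSA, the paired rows,
and the gap-padded unpaired rows — so that regions the full-length search
covers poorly inherit depth from the domain searches.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Msa",
    "DomainSegmentation",
    "DepthProfile",
    "read_a3m",
    "write_a3m",
    "depth_profile",
    "slice_msa",
    "build_domain_msa",
    "batch_domain_msas",
]


def match_length(aligned: str) -> int:
    """Number of match columns (uppercase residues or '-') in an A3M row."""
    return sum(1 for c in aligned if c == "-" or c.isupper())


@dataclass
class Msa:
    """A query plus aligned homolog rows in A3M convention.

    ``rows`` holds the non-query records; the query is stored separately and
    is written first on output. Uppercase and '-' are match columns against
    the query, lowercase characters are insertions.
    """

    query_id: str
    query_seq: str
    rows: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if "-" in self.query_seq or not self.query_seq.isupper():
            raise ValueError("query row must be ungapped uppercase")
        L = len(self.query_seq)
        seen: set[str] = set()
        for ident, seq in self.rows:
            if ident in seen:
                raise ValueError(f"duplicate identifier {ident!r} in MSA")
            seen.add(ident)
            m = match_length(seq)
            if m != L:
                raise ValueError(
                    f"row {ident!r} has {m} match columns, query length is {L}"
                )

    def __len__(self) -> int:
        """Number of sequences including the query."""
        return 1 + len(self.rows)

    @property
    def L(self) -> int:
        return len(self.query_seq)


@dataclass
class DomainSegmentation:
    """Ordered, non-overlapping 1-based inclusive ranges in target coordinates."""

    method: str
    ranges: list[tuple[int, int]]

    def __post_init__(self) -> None:
        self.ranges = [(int(s), int(e)) for s, e in self.ranges]
        prev_end = 0
        for s, e in self.ranges:
            if s < 1 or e < s:
                raise ValueError(f"invalid range ({s}, {e})")
            if s <= prev_end:
                raise ValueError("ranges must be increasing and non-overlapping")
            prev_end = e

    def validate_against(self, L: int) -> None:
        if self.ranges and self.ranges[-1][1] > L:
            raise ValueError(f"segmentation exceeds target length {L}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"method": self.method, "ranges": [list(r) for r in self.ranges]})
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "DomainSegmentation":
        obj = json.loads(Path(path).read_text())
        return cls(method=obj["method"], ranges=[tuple(r) for r in obj["ranges"]])


@dataclass
class DepthProfile:
    """Per-match-column count of rows with an aligned (non-gap) residue."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)

    def mean(self, start: int | None = None, end: int | None = None) -> float:
        """Mean depth over a 1-based inclusive residue range (default: all)."""
        s = 1 if start is None else start
        e = len(self.counts) if end is None else end
        if not (1 <= s <= e <= len(self.counts)):
            raise ValueError(f"range ({s}, {e}) outside profile of length {len(self.counts)}")
        return float(self.counts[s - 1 : e].mean())

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("position\tdepth\n")
            for i, c in enumerate(self.counts, start=1):
                fh.write(f"{i}\t{int(c)}\n")


def _parse_fasta(text: str) -> list[tuple[str, str]]:
    records: list[tuple[str, str]] = []
    header: str | None = None
    chunks: list[str] = []
    for line in text.splitlines():
        line = line.rstrip()
        if not line or line.startswith("#"):
            continue
        if line.startswith(">"):
            if header is not None:
                records.append((header, "".join(chunks)))
            header = line[1:].split()[0] if len(line) > 1 else ""
            chunks = []
        elif header is not None:
            chunks.append(line)
    if header is not None:
        records.append((header, "".join(chunks)))
    return records


def read_a3m(path: str | Path) -> Msa:
    """Read an A3M/aligned-FASTA file; the first record is the query.

    '.' insertion-gap characters are dropped (they carry no sequence). Each
    row's match-column count is validated against the query length.
    """
    records = _parse_fasta(Path(path).read_text())
    if not records:
        raise ValueError(f"{path}: empty alignment")
    qid, qseq = records[0]
    qseq = qseq.replace(".", "")
    rows = [(i, s.replace(".", "")) for i, s in records[1:]]
    try:
        return Msa(query_id=qid, query_seq=qseq, rows=rows)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_a3m(msa: Msa, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{msa.query_id}\n{msa.query_seq}\n")
        for ident, seq in msa.rows:
            fh.write(f">{ident}\n{seq}\n")


def _match_mask(aligned: str) -> np.ndarray:
    """Boolean per match column: True where the row has an aligned residue."""
    return np.fromiter(
        (c != "-" for c in aligned if c == "-" or c.isupper()), dtype=bool
    )


def depth_profile(msa: Msa, include_query: bool = True) -> DepthProfile:
    """Alignment depth at each query position (query counted iff requested)."""
    counts = np.zeros(msa.L, dtype=int)
    if include_query:
        counts += 1
    for _, seq in msa.rows:
        counts += _match_mask(seq)
    return DepthProfile(counts=counts)


def _slice_row(aligned: str, start: int, end: int) -> str:
    """Keep match columns start..end (1-based) and insertions internal to them."""
    out: list[str] = []
    mc = 0
    for c in aligned:
        if c == "-" or c.isupper():
            mc += 1
            if start <= mc <= end:
                out.append(c)
        else:  # lowercase insertion: internal iff between kept match columns
            if start <= mc < end:
                out.append(c)
    return "".join(out)


def slice_msa(msa: Msa, rng: tuple[int, int]) -> Msa:
    """Restrict an MSA to match columns ``rng`` (1-based inclusive).

    Rows left without any aligned residue are dropped.
    """
    start, end = int(rng[0]), int(rng[1])
    if not (1 <= start <= end <= msa.L):
        raise ValueError(f"range ({start}, {end}) invalid for query length {msa.L}")
    rows: list[tuple[str, str]] = []
    for ident, seq in msa.rows:
        sl = _slice_row(seq, start, end)
        if any(c != "-" for c in sl):
            rows.append((ident, sl))
    return Msa(query_id=msa.query_id, query_seq=msa.query_seq[start - 1 : end], rows=rows)


def build_domain_msa(
    full: Msa,
    domain_msas: list[Msa],
    seg: DomainSegmentation,
) -> Msa:
    """Assemble the three-block combined MSA for one (segmentation, full-MSA) pair.

    Block order: (1) every row of ``full``; (2) paired rows — identifiers
    shared by >= 2 domain MSAs, each domain's aligned residues placed into its
    range; (3) unpaired rows gap-padded outside their single domain. Linker
    columns of blocks (2) and (3) are '-'. The query appears exactly once, as
    the full target sequence.
    """
    L = full.L
    seg.validate_against(L)
    if len(domain_msas) != len(seg.ranges):
        raise ValueError(
            f"{len(domain_msas)} domain MSAs for {len(seg.ranges)} ranges"
        )
    for dm, (s, e) in zip(domain_msas, seg.ranges):
        expected = full.query_seq[s - 1 : e]
        if dm.query_seq != expected:
            raise ValueError(
                f"domain MSA query for range ({s}, {e}) is {dm.query_seq!r}, "
                f"target slice is {expected!r}"
            )

    # identifier -> list of (domain index, aligned row); domain queries excluded
    hits: dict[str, list[tuple[int, str]]] = {}
    order: list[str] = []
    for di, dm in enumerate(domain_msas):
        for ident, seq in dm.rows:
            if ident == dm.query_id:
                continue
            if ident not in hits:
                hits[ident] = []
                order.append(ident)
            if any(d == di for d, _ in hits[ident]):
                warnings.warn(f"identifier {ident!r} duplicated in domain {di}; keeping first")
                continue
            hits[ident].append((di, seq))

    def assemble(row_hits: list[tuple[int, str]]) -> str:
        present = dict(row_hits)
        parts: list[str] = []
        pos = 1
        for di, (s, e) in enumerate(seg.ranges):
            if s > pos:
                parts.append("-" * (s - pos))
            parts.append(present.get(di, "-" * (e - s + 1)))
            pos = e + 1
        if pos <= L:
            parts.append("-" * (L - pos + 1))
        return "".join(parts)

    paired = [(i, assemble(hits[i])) for i in order if len(hits[i]) >= 2]
    unpaired = [(i, assemble(hits[i])) for i in order if len(hits[i]) == 1]
    logger.info(
        "domain MSA %s: %d full rows, %d paired, %d unpaired",
        seg.method, len(full.rows), len(paired), len(unpaired),
    )

    rows: list[tuple[str, str]] = []
    seen: set[str] = set()
    for block, tag in ((full.rows, "full"), (paired, "paired"), (unpaired, "unpaired")):
        for ident, seq in block:
            if ident == full.query_id:
                continue  # query appears once, as row 0
            name = ident if ident not in seen else f"{ident}|{tag}"
            seen.add(ident)
            rows.append((name, seq))
    return Msa(query_id=full.query_id, query_seq=full.query_seq, rows=rows)


def batch_domain_msas(
    full_sources: dict[str, Msa],
    segs: list[DomainSegmentation],
    domain_msas_per: dict[str, list[Msa] | dict[str, list[Msa]]],
) -> dict[str, Msa]:
    """One combined MSA per (segmentation, full-length source), named
    ``<method>__<source>``.

    ``domain_msas_per`` maps a segmentation method to its per-range domain
    MSAs, either one list used with every source or a per-source dict.
    """
    if not segs:
        warnings.warn("no segmentations given; returning empty collection")
        return {}
    out: dict[str, Msa] = {}
    for seg in segs:
        per = domain_msas_per[seg.method]
        for source, full in full_sources.items():
            dms = per[source] if isinstance(per, dict) else per
            out[f"{seg.method}__{source}"] = build_domain_msa(full, dms, seg)
    return out
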