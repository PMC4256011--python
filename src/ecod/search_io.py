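"""Normalized homology evidence: one Hit record for every search method.

The partition pipeline consumes evidence from four different programs —
whole-chain and per-domain BLAST (tabular output), HHsearch profile-profile
comparison (HHR reports), DALI structure search, and HMMER3 Pfam scans
(domtblout).  Each parser here maps its native format onto the same
:class:`Hit` record so that downstream threshold logic never needs to know
which program produced the evidence.

Notes on formats:

* BLAST: the standard 12-column tabular layout (fmt 6, or fmt 7 with ``#``
  comment lines) is assumed: qseqid sseqid pident length mismatch gapopen
  qstart qend sstart send evalue bitscore.
* HHR: probabilities are kept on the percent scale (0-100) exactly as
  printed by HHsearch; every threshold in the pipeline configuration uses
  the same scale.
* DALI: native DaliLite output is not a stable format.  This module defines
  a simplified TSV dialect (``query_id target_id z_score rmsd nalign pairs``
  with ``pairs`` a comma-joined list of ``qpos:tpos``) and a matching writer;
  converting real DaliLite output into the dialect is a documented external
  contract.
* domtblout: the HMMER3 per-domain table; the independent E-value (i-Evalue)
  column and the envelope coordinates are the fields that matter for family
  assignment.

Writers for the internal dialects are provided so that fixture files can be
round-tripped bit-exactly (write -> parse -> write).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, TextIO, Union

import numpy as np

from .ranges import SegmentSet

__all__ = [
    "Hit",
    "CoordSet",
    "SearchIOError",
    "parse_blast_tabular",
    "write_blast_tabular",
    "parse_hhr",
    "write_hhr",
    "parse_dali_rows",
    "write_dali_rows",
    "parse_hmmer_domtblout",
    "write_hmmer_domtblout",
    "read_ca_coordinates",
    "read_fasta",
    "write_fasta",
]


class SearchIOError(ValueError):
    """Malformed search output or coordinate file."""


@dataclass(frozen=True)
class Hit:
    """One normalized piece of homology evidence.

    ``aligned_pairs`` holds (query_pos, target_pos) residue correspondences,
    1-based on SEQRES numbering, strictly increasing in both coordinates.
    At least one of evalue / probability / z_score must be present.
    """

    query_id: str
    query_range: SegmentSet
    target_id: str
    target_kind: str  # chain | domain | profile | structure
    method: str  # chain_blast | domain_blast | hhsearch | dali | hmmer
    evalue: Optional[float] = None
    probability: Optional[float] = None  # percent scale, as printed
    z_score: Optional[float] = None
    identity: Optional[float] = None  # percent
    aligned_pairs: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        if self.evalue is None and self.probability is None and self.z_score is None:
            raise SearchIOError(
                f"hit {self.query_id}->{self.target_id}: no score present"
            )
        prev_q = prev_t = 0
        for q, t in self.aligned_pairs:
            if q <= prev_q or t <= prev_t:
                raise SearchIOError(
                    f"hit {self.query_id}->{self.target_id}: aligned_pairs not "
                    f"strictly increasing at ({q},{t})"
                )
            prev_q, prev_t = q, t

    @property
    def target_range(self) -> SegmentSet:
        """Target-side footprint of the alignment (from aligned_pairs)."""
        return SegmentSet.from_positions(
            (self.target_id, t) for _, t in self.aligned_pairs
        )


def _as_stream(stream: Union[TextIO, str]) -> TextIO:
    return io.StringIO(stream) if isinstance(stream, str) else stream


def _linear_pairs(qstart: int, qend: int, sstart: int, send: int):
    """Co-linear 1:1 correspondence for an ungapped-style tabular hit."""
    n = min(qend - qstart, send - sstart) + 1
    return tuple((qstart + i, sstart + i) for i in range(n))


# ---------------------------------------------------------------------------
# BLAST tabular


def parse_blast_tabular(
    stream: Union[TextIO, str],
    method: str = "domain_blast",
) -> list[Hit]:
    """Parse 12-column BLAST tabular output (fmt 6/7).

    ``method`` records the caller's context: ``chain_blast`` when the library
    searched was full-length chains, ``domain_blast`` for the domain library.
    """
    if method not in ("chain_blast", "domain_blast"):
        raise SearchIOError(f"unknown BLAST context {method!r}")
    hits: list[Hit] = []
    target_kind = "chain" if method == "chain_blast" else "domain"
    for lineno, raw in enumerate(_as_stream(stream), start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 12:
            raise SearchIOError(f"line {lineno}: expected 12 columns, got {len(fields)}")
        try:
            pident = float(fields[2])
            qstart, qend = int(fields[6]), int(fields[7])
            sstart, send = int(fields[8]), int(fields[9])
            evalue = float(fields[10])
        except ValueError as exc:
            raise SearchIOError(f"line {lineno}: non-numeric field ({exc})") from exc
        hits.append(
            Hit(
                query_id=fields[0],
                query_range=SegmentSet.single(fields[0], qstart, qend),
                target_id=fields[1],
                target_kind=target_kind,
                method=method,
                evalue=evalue,
                identity=pident,
                aligned_pairs=_linear_pairs(qstart, qend, sstart, send),
            )
        )
    return hits


def write_blast_tabular(hits: Iterable[Hit], stream: TextIO) -> None:
    for hit in hits:
        (chain, qstart, qend), *_rest = hit.query_range.segments
        tpos = [t for _, t in hit.aligned_pairs]
        sstart, send = (tpos[0], tpos[-1]) if tpos else (qstart, qend)
        length = qend - qstart + 1
        stream.write(
            "\t".join(
                (
                    hit.query_id,
                    hit.target_id,
                    f"{hit.identity if hit.identity is not None else 100.0:.2f}",
                    str(length),
                    "0",
                    "0",
                    str(qstart),
                    str(qend),
                    str(sstart),
                    str(send),
                    f"{hit.evalue:.3g}",
                    "0.0",
                )
            )
            + "\n"
        )


# ---------------------------------------------------------------------------
# HHsearch HHR


def _format_evalue(value: float) -> str:
    return f"{value:.3g}"


def write_hhr(
    stream: TextIO,
    query_id: str,
    query_seq: str,
    hits: Sequence[Hit],
    target_seqs: Mapping[str, str],
) -> None:
    """Write a canonical HHR report for one query.

    Alignment blocks are reconstructed from ``aligned_pairs``; unpaired
    positions between consecutive pairs become gap columns.
    """
    stream.write(f"Query         {query_id}\n")
    stream.write(f"Match_columns {len(query_seq)}\n")
    stream.write("No_of_seqs    1 out of 1\n\n")
    stream.write(
        " No Hit                             Prob E-value P-value  Score    SS "
        "Cols Query HMM  Template HMM\n"
    )
    for i, hit in enumerate(hits, start=1):
        qpos = [q for q, _ in hit.aligned_pairs]
        tpos = [t for _, t in hit.aligned_pairs]
        stream.write(
            f"{i:>3} {hit.target_id:<30} {hit.probability:5.1f} "
            f"{_format_evalue(hit.evalue):>8} {1.0:7.2g} {0.0:6.1f} {0.0:5.1f} "
            f"{len(qpos):4d} {qpos[0]}-{qpos[-1]:<9} {tpos[0]}-{tpos[-1]}\n"
        )
    stream.write("\n")
    for i, hit in enumerate(hits, start=1):
        tseq = target_seqs[hit.target_id]
        q_chars: list[str] = []
        t_chars: list[str] = []
        prev_q, prev_t = None, None
        for q, t in hit.aligned_pairs:
            if prev_q is not None:
                for skip in range(prev_q + 1, q):
                    q_chars.append(query_seq[skip - 1])
                    t_chars.append("-")
                for skip in range(prev_t + 1, t):
                    q_chars.append("-")
                    t_chars.append(tseq[skip - 1])
            q_chars.append(query_seq[q - 1])
            t_chars.append(tseq[t - 1])
            prev_q, prev_t = q, t
        qstart, qend = hit.aligned_pairs[0][0], hit.aligned_pairs[-1][0]
        tstart, tend = hit.aligned_pairs[0][1], hit.aligned_pairs[-1][1]
        identity = hit.identity if hit.identity is not None else 0.0
        stream.write(f"No {i}\n")
        stream.write(f">{hit.target_id}\n")
        stream.write(
            f"Probab={hit.probability:.2f}  E-value={_format_evalue(hit.evalue)}  "
            f"Score=0.00  Aligned_cols={len(hit.aligned_pairs)}  "
            f"Identities={identity:.0f}%  Similarity=0.000  Sum_probs=0.0\n\n"
        )
        stream.write(
            f"Q {query_id:<14}{qstart:>4} {''.join(q_chars)} {qend:>4} ({len(query_seq)})\n"
        )
        stream.write(
            f"T {hit.target_id:<14}{tstart:>4} {''.join(t_chars)} {tend:>4} ({len(tseq)})\n"
        )
        stream.write("\n")


_HHR_SKIP_NAMES = {"Consensus", "ss_pred", "ss_conf", "ss_dssp"}


def parse_hhr(stream: Union[TextIO, str]) -> list[Hit]:
    """Parse an HHR report into Hits (probability on the percent scale).

    Residue correspondences are rebuilt from the alignment blocks: a pair is
    recorded for every column in which both query and template have a residue.
    Multi-segment alignments (several Q/T line groups per hit) concatenate.
    """
    lines = _as_stream(stream).read().splitlines()
    query_id = None
    for line in lines:
        if line.startswith("Query "):
            query_id = line.split(maxsplit=1)[1].split()[0]
            break
    hits: list[Hit] = []
    current: Optional[dict] = None
    pending_q: Optional[tuple[int, str]] = None

    def finish(block: Optional[dict]):
        if block is None:
            return
        if pending_q is not None:
            raise SearchIOError(
                f"truncated alignment block in hit {block.get('target')!r}"
            )
        if block.get("probability") is None:
            raise SearchIOError(f"hit {block.get('target')!r} lacks a Probab line")
        pairs = tuple(block["pairs"])
        qpositions = [q for q, _ in pairs]
        hits.append(
            Hit(
                query_id=query_id or "query",
                query_range=SegmentSet.from_positions(
                    (query_id or "query", q) for q in qpositions
                ),
                target_id=block["target"],
                target_kind="profile",
                method="hhsearch",
                evalue=block.get("evalue"),
                probability=block["probability"],
                identity=block.get("identity"),
                aligned_pairs=pairs,
            )
        )

    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if stripped.startswith("No ") and stripped[3:].strip().isdigit():
            finish(current)
            current = {"pairs": [], "target": None}
            pending_q = None
            continue
        if current is None:
            continue
        if stripped.startswith(">") and current["target"] is None:
            current["target"] = stripped[1:].split()[0]
            continue
        if stripped.startswith("Probab="):
            for token in stripped.split():
                if "=" not in token:
                    continue
                key, _, value = token.partition("=")
                try:
                    if key == "Probab":
                        current["probability"] = float(value)
                    elif key == "E-value":
                        current["evalue"] = float(value)
                    elif key == "Identities":
                        current["identity"] = float(value.rstrip("%"))
                except ValueError as exc:
                    raise SearchIOError(f"line {lineno}: bad {key} value") from exc
            continue
        if stripped.startswith(("Q ", "T ")):
            tokens = stripped.split()
            if len(tokens) < 5 or tokens[1] in _HHR_SKIP_NAMES:
                continue
            try:
                start = int(tokens[2])
                seq = tokens[3]
            except ValueError:
                continue
            if stripped.startswith("Q "):
                if pending_q is not None:
                    raise SearchIOError(f"line {lineno}: two query lines in a row")
                pending_q = (start, seq)
            else:
                if pending_q is None:
                    raise SearchIOError(f"line {lineno}: template line without query")
                qstart, qseq = pending_q
                pending_q = None
                if len(qseq) != len(seq):
                    raise SearchIOError(
                        f"line {lineno}: alignment rows differ in length"
                    )
                qpos, tpos = qstart, start
                for qc, tc in zip(qseq, seq):
                    if qc != "-" and tc != "-":
                        current["pairs"].append((qpos, tpos))
                    if qc != "-":
                        qpos += 1
                    if tc != "-":
                        tpos += 1
    finish(current)
    return hits


# ---------------------------------------------------------------------------
# DALI dialect

_DALI_COLUMNS = ("query_id", "target_id", "z_score", "rmsd", "nalign", "pairs")


def parse_dali_rows(stream: Union[TextIO, str]) -> list[Hit]:
    """Parse the internal DALI TSV dialect (see module docstring)."""
    hits: list[Hit] = []
    handle = _as_stream(stream)
    header = handle.readline().rstrip("\n")
    if not header:
        return []
    if tuple(header.split("\t")) != _DALI_COLUMNS:
        raise SearchIOError(f"DALI dialect header mismatch: {header!r}")
    for lineno, raw in enumerate(handle, start=2):
        line = raw.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) != len(_DALI_COLUMNS):
            raise SearchIOError(f"line {lineno}: expected {len(_DALI_COLUMNS)} columns")
        if not fields[2]:
            raise SearchIOError(f"line {lineno}: missing z_score")
        try:
            z = float(fields[2])
            pairs = tuple(
                (int(p.split(":")[0]), int(p.split(":")[1]))
                for p in fields[5].split(",")
                if p
            )
        except ValueError as exc:
            raise SearchIOError(f"line {lineno}: {exc}") from exc
        hits.append(
            Hit(
                query_id=fields[0],
                query_range=SegmentSet.from_positions(
                    (fields[0], q) for q, _ in pairs
                ),
                target_id=fields[1],
                target_kind="structure",
                method="dali",
                z_score=z,
                aligned_pairs=pairs,
            )
        )
    return hits


def write_dali_rows(hits: Iterable[Hit], stream: TextIO) -> None:
    stream.write("\t".join(_DALI_COLUMNS) + "\n")
    for hit in hits:
        pairs = ",".join(f"{q}:{t}" for q, t in hit.aligned_pairs)
        stream.write(
            "\t".join(
                (
                    hit.query_id,
                    hit.target_id,
                    f"{hit.z_score:.1f}",
                    "0.00",
                    str(len(hit.aligned_pairs)),
                    pairs,
                )
            )
            + "\n"
        )


# ---------------------------------------------------------------------------
# HMMER3 domtblout

_DOMTBL_MIN_FIELDS = 23


def parse_hmmer_domtblout(stream: Union[TextIO, str]) -> list[Hit]:
    """Parse an HMMER3 per-domain table.

    The E-value recorded is the independent (i-Evalue) column; the query
    range is the envelope.  The target is the profile (Pfam accession when
    available, otherwise the model name).
    """
    hits: list[Hit] = []
    for lineno, raw in enumerate(_as_stream(stream), start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < _DOMTBL_MIN_FIELDS:
            raise SearchIOError(
                f"line {lineno}: expected >= {_DOMTBL_MIN_FIELDS} columns, "
                f"got {len(fields)}"
            )
        target_name, target_acc = fields[0], fields[1]
        query_name = fields[3]
        try:
            ievalue = float(fields[12])
            env_from, env_to = int(fields[19]), int(fields[20])
        except ValueError as exc:
            raise SearchIOError(f"line {lineno}: non-numeric field ({exc})") from exc
        if env_from > env_to:
            raise SearchIOError(
                f"line {lineno}: envelope start {env_from} > end {env_to}"
            )
        target = target_acc if target_acc not in ("", "-") else target_name
        hits.append(
            Hit(
                query_id=query_name,
                query_range=SegmentSet.single(query_name, env_from, env_to),
                target_id=target,
                target_kind="profile",
                method="hmmer",
                evalue=ievalue,
            )
        )
    return hits


def write_hmmer_domtblout(hits: Iterable[Hit], stream: TextIO) -> None:
    """Write the internal single-space-separated domtblout dialect."""
    stream.write(
        "# target name accession tlen query name accession qlen E-value score "
        "bias # of c-Evalue i-Evalue score bias from to from to from to acc "
        "description\n"
    )
    for hit in hits:
        (chain, start, end), *_ = hit.query_range.segments
        ev = f"{hit.evalue:.3g}"
        stream.write(
            " ".join(
                (
                    hit.target_id,
                    hit.target_id,
                    "0",
                    hit.query_id,
                    "-",
                    "0",
                    ev,
                    "0.0",
                    "0.0",
                    "1",
                    "1",
                    ev,
                    ev,
                    "0.0",
                    "0.0",
                    str(start),
                    str(end),
                    str(start),
                    str(end),
                    str(start),
                    str(end),
                    "0.99",
                    "-",
                )
            )
            + "\n"
        )


# ---------------------------------------------------------------------------
# Coordinates and sequences


@dataclass
class CoordSet:
    """Per-residue CA coordinates keyed by (chain_id, seqres index), in Å."""

    coords: dict[tuple[str, int], np.ndarray] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.coords)

    def __getitem__(self, key: tuple[str, int]) -> np.ndarray:
        return self.coords[key]

    def __contains__(self, key: tuple[str, int]) -> bool:
        return key in self.coords

    def add(self, chain: str, index: int, xyz) -> None:
        xyz = np.asarray(xyz, dtype=float)
        if not np.all(np.isfinite(xyz)) or xyz.shape != (3,):
            raise SearchIOError(f"non-finite coordinate for {chain}:{index}")
        if (chain, index) in self.coords:
            raise SearchIOError(f"duplicate coordinate key {chain}:{index}")
        self.coords[(chain, index)] = xyz

    def chain_array(self, chain: str) -> tuple[list[int], np.ndarray]:
        """Sorted residue indices and an (n, 3) array for one chain."""
        indices = sorted(i for c, i in self.coords if c == chain)
        arr = np.array([self.coords[(chain, i)] for i in indices], dtype=float)
        return indices, arr


def read_ca_coordinates(path) -> CoordSet:
    """Extract one CA position per residue from a PDB or mmCIF file.

    The first alternate location encountered wins.  Residues without a
    carbon CA atom (ligands, ions — including calcium, whose atom is also
    named CA but is not a carbon) are skipped; a file yielding no CA atoms
    at all is rejected.
    """
    import gemmi

    structure = gemmi.read_structure(str(path))
    structure.setup_entities()
    coords = CoordSet()
    if len(structure) == 0:
        raise SearchIOError(f"{path}: no models")
    model = structure[0]
    for chain in model:
        for residue in chain:
            ca = None
            for atom in residue:
                if atom.name == "CA" and atom.element.name == "C":
                    ca = atom
                    break
            if ca is None:
                continue
            label_seq = residue.label_seq
            index = label_seq if label_seq is not None else residue.seqid.num
            key = (chain.name, int(index))
            if key in coords:
                continue  # extra altloc copies of the residue
            coords.add(chain.name, int(index), [ca.pos.x, ca.pos.y, ca.pos.z])
    if len(coords) == 0:
        raise SearchIOError(f"{path}: no CA atoms found")
    return coords


def read_fasta(stream: Union[TextIO, str]) -> dict[str, str]:
    """FASTA -> {id: sequence} preserving input order."""
    from Bio import SeqIO

    handle = _as_stream(stream)
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(handle, "fasta")}


def write_fasta(sequences: Mapping[str, str], stream: TextIO, width: int = 60) -> None:
    for name, seq in sequences.items():
        stream.write(f">{name}\n")
        for i in range(0, len(seq), width):
            stream.write(seq[i : i + width] + "\n")
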