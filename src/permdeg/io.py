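"""Readers and writers for the pipeline's text formats.

Expression tables are TSV with the gene id in the first column and a
``# scale=<tag>`` comment line recording the matrix scale. Designs are
2-column TSV (sample, group) with a ``# reference=<group>`` comment. Gene
sets use GMT, TF maps 2-column TSV, sequences FASTA (via Biopython),
position frequency matrices the JASPAR flat-file dialects, and interaction
lists SIF or 4-column TSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .containers import SCALE_FPKM, VALID_SCALES, ExpressionMatrix, GroupDesign
from .enrichment import GeneSetCollection
from .errors import FormatError
from .motifs import (
    PositionFrequencyMatrix,
    format_jaspar,
    parse_jaspar_all,
)
from .network import _SIF_INVERSE, _SIF_TOKEN, Edge

# --- expression matrices ---------------------------------------------------


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# scale={matrix.scale}\n")
        matrix.data.to_csv(fh, sep="\t", index_label="gene_id")


def read_expression(path: str | Path) -> ExpressionMatrix:
    path = Path(path)
    scale = SCALE_FPKM
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# scale="):
            scale = first.strip().split("=", 1)[1]
            if scale not in VALID_SCALES:
                raise FormatError(f"unknown scale tag {scale!r}", line=1)
            skip = 1
        else:
            skip = 0
    frame = pd.read_csv(path, sep="\t", skiprows=skip, index_col=0)
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()][0]
        raise FormatError(f"duplicate gene id {dup!r}")
    try:
        frame = frame.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric expression value: {exc}") from exc
    frame.index = frame.index.astype(str)
    return ExpressionMatrix(frame, scale)


# --- designs ---------------------------------------------------------------


def write_design(design: GroupDesign, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# reference={design.reference}\n")
        fh.write("sample\tgroup\n")
        for sample, group in design.groups.items():
            fh.write(f"{sample}\t{group}\n")


def read_design(path: str | Path, reference: str | None = None) -> GroupDesign:
    groups: dict[str, str] = {}
    header_seen = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("# reference=") and reference is None:
                    reference = line.split("=", 1)[1].strip()
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError("design rows need exactly 2 fields", lineno)
            if not header_seen and parts == ["sample", "group"]:
                header_seen = True
                continue
            sample, group = parts
            if sample in groups:
                raise FormatError(f"duplicate sample {sample!r}", lineno)
            groups[sample] = group
    if reference is None:
        raise FormatError("no reference group given (missing '# reference=')")
    return GroupDesign(groups=groups, reference=reference)


# --- gene sets (GMT) -------------------------------------------------------


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for set_id in collection:
            members = "\t".join(collection[set_id])
            fh.write(f"{set_id}\t{collection.description(set_id)}\t{members}\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"GMT rows need >= 3 fields, got {len(parts)}", lineno
                )
            set_id, description, *members = parts
            if set_id in sets:
                raise FormatError(f"duplicate gene set {set_id!r}", lineno)
            members = [m for m in members if m]
            if not members:
                raise FormatError(f"gene set {set_id!r} has no members", lineno)
            sets[set_id] = members
            descriptions[set_id] = description
    return GeneSetCollection(sets, descriptions)


# --- TF -> target maps -----------------------------------------------------


def write_tf_map(tf_map: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("tf\ttarget\n")
        for tf in tf_map:
            for target in tf_map[tf]:
                fh.write(f"{tf}\t{target}\n")


def read_tf_map(path: str | Path) -> dict[str, list[str]]:
    tf_map: dict[str, list[str]] = {}
    header_seen = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError("TF map rows need exactly 2 fields", lineno)
            if not header_seen and parts == ["tf", "target"]:
                header_seen = True
                continue
            tf, target = parts
            bucket = tf_map.setdefault(tf, [])
            if target not in bucket:
                bucket.append(target)
    return tf_map


# --- FASTA -----------------------------------------------------------------


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=seq_id, description="")
        for seq_id, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise FormatError(f"duplicate FASTA id {record.id!r}")
        sequences[record.id] = str(record.seq).upper()
    return sequences


# --- JASPAR ----------------------------------------------------------------


def read_jaspar(path: str | Path) -> list[PositionFrequencyMatrix]:
    return parse_jaspar_all(Path(path).read_text())


def write_jaspar(
    motifs: Sequence[PositionFrequencyMatrix], path: str | Path
) -> None:
    Path(path).write_text("".join(format_jaspar(m) for m in motifs))


# --- interaction edges -----------------------------------------------------


def write_edges_tsv(edges: Sequence, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("source\ttarget\tedge_type\tevidence\n")
        for item in edges:
            e = item if isinstance(item, Edge) else Edge(*tuple(item))
            fh.write(f"{e.source}\t{e.target}\t{e.edge_type}\t{e.evidence}\n")


def read_edges_tsv(path: str | Path) -> list[Edge]:
    edges: list[Edge] = []
    header_seen = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if not 2 <= len(parts) <= 4:
                raise FormatError("edge rows need 2-4 fields", lineno)
            if not header_seen and parts[:2] == ["source", "target"]:
                header_seen = True
                continue
            try:
                edges.append(Edge(*parts))
            except ValueError as exc:
                raise FormatError(str(exc), lineno) from exc
    return edges


def write_sif(edges: Sequence, path: str | Path) -> None:
    with open(path, "w") as fh:
        for item in edges:
            e = item if isinstance(item, Edge) else Edge(*tuple(item))
            fh.write(f"{e.source}\t{_SIF_TOKEN[e.edge_type]}\t{e.target}\n")


def read_sif(path: str | Path) -> list[Edge]:
    edges: list[Edge] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 3:
                raise FormatError("SIF rows need 3 whitespace fields", lineno)
            source, token, target = parts
            if token not in _SIF_INVERSE:
                raise FormatError(f"unknown SIF relation {token!r}", lineno)
            edges.append(Edge(source, target, _SIF_INVERSE[token]))
    return edges


# --- results ---------------------------------------------------------------


def write_json(payload: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
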