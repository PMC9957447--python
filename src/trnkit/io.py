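"""Readers and writers for the standard formats the pipeline touches.

Expression tables and TF lists are plain TSV/CSV and text; promoters are
FASTA (Bio.SeqIO); the ontology is OBO (obonet); gene->term annotations are
GAF 2.x or two-column TSV; PWMs use MEME minimal format; networks are TSV
edge lists with an optional GraphML export.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.UniProt import GOA

import obonet

from .datamodel import (
    NUCLEOTIDES,
    ExpressionMatrix,
    GOCorpus,
    PWM,
    RegulatoryNetwork,
    TrnkitError,
    warn,
)


def _sep_for(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_tf_list(path: str | Path) -> list[str]:
    """One TF identifier per line; blank lines ignored."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def read_expression(
    path: str | Path,
    tf_list_path: str | Path,
    *,
    impute_missing: bool = False,
    sample_category: Mapping[str, str] | None = None,
) -> ExpressionMatrix:
    """Load an expression table plus TF list into an :class:`ExpressionMatrix`.

    The table must have a header row of sample ids and gene ids in the first
    column. TFs absent from the table are dropped with a warning. Missing
    values are rejected unless ``impute_missing`` (row-mean imputation).
    """
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise TrnkitError(f"duplicate gene ids in {path}: {dups[:5]}")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            row = bad.index[0] if len(bad) else "?"
            raise TrnkitError(f"non-numeric expression value at gene {row}, sample {col}")
    if df.isna().any().any():
        if not impute_missing:
            raise TrnkitError("missing expression values (pass impute_missing=True to row-mean impute)")
        means = df.mean(axis=1)
        df = df.apply(lambda row: row.fillna(means[row.name]), axis=1)

    tf_ids = read_tf_list(tf_list_path)
    present = [t for t in tf_ids if t in df.index]
    absent = [t for t in tf_ids if t not in df.index]
    if absent:
        warn(f"{len(absent)} of {len(tf_ids)} TFs have no expression data and were dropped")
    if not present:
        raise TrnkitError("no usable TF features")
    cat = dict(sample_category) if sample_category is not None else None
    return ExpressionMatrix(df, present, cat)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.values.to_csv(path, sep=_sep_for(path), index_label="gene_id")


# ---------------------------------------------------------------------------
# MEME minimal format PWMs

_MOTIF_RE = re.compile(r"^MOTIF\s+(\S+)")
_LPM_RE = re.compile(r"letter-probability matrix.*?(?:w=\s*(\d+))?\s*(?:nsites|E)?", re.I)


def read_pwms(path: str | Path) -> list[PWM]:
    """Parse a MEME minimal-format file into a list of :class:`PWM`.

    Background frequencies are taken from the header when present, else
    uniform. Columns off unit sum by more than 1e-3 are renormalized with a
    warning.
    """
    lines = Path(path).read_text().splitlines()
    background = np.full(4, 0.25)
    pwms: list[PWM] = []
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("ALPHABET"):
            alpha = line.split("=", 1)[-1].strip()
            if alpha.upper() != "ACGT":
                raise TrnkitError(f"unsupported alphabet {alpha!r} (only ACGT)")
        elif line.lower().startswith("background letter frequencies"):
            i += 1
            tokens: list[str] = []
            while i < len(lines) and lines[i].strip() and not lines[i].startswith("MOTIF"):
                tokens.extend(lines[i].split())
                i += 1
            freqs = {tokens[j].upper(): float(tokens[j + 1]) for j in range(0, len(tokens), 2)}
            background = np.array([freqs.get(nt, 0.25) for nt in NUCLEOTIDES])
            background = background / background.sum()
            continue
        m = _MOTIF_RE.match(line)
        if m:
            motif_id = m.group(1)
            i += 1
            while i < len(lines) and "letter-probability matrix" not in lines[i]:
                i += 1
            if i >= len(lines):
                raise TrnkitError(f"motif {motif_id}: missing letter-probability matrix")
            wm = re.search(r"w=\s*(\d+)", lines[i])
            i += 1
            rows: list[list[float]] = []
            while i < len(lines):
                stripped = lines[i].strip()
                if not stripped or stripped.startswith(("MOTIF", "URL")):
                    break
                parts = stripped.split()
                if len(parts) != 4:
                    break
                rows.append([float(x) for x in parts])
                i += 1
            if wm is not None and len(rows) != int(wm.group(1)):
                raise TrnkitError(f"motif {motif_id}: expected w={wm.group(1)} rows, got {len(rows)}")
            mat = np.array(rows).T  # file rows are positions; we store 4 x t
            sums = mat.sum(axis=0)
            off = np.abs(sums - 1.0) > 1e-3
            if off.any():
                warn(f"motif {motif_id}: {int(off.sum())} column(s) renormalized to unit sum")
            mat = mat / sums
            pwms.append(PWM(mat, background=background.copy(), id=motif_id))
            continue
        i += 1
    return pwms


def write_pwms(pwms: Iterable[PWM], path: str | Path, background: np.ndarray | None = None) -> None:
    """Write PWMs in MEME minimal format (one shared background line)."""
    pwms = list(pwms)
    if background is None:
        background = pwms[0].background if pwms else np.full(4, 0.25)
    out = ["MEME version 4", "", "ALPHABET= ACGT", "", "Background letter frequencies"]
    out.append(" ".join(f"{nt} {b:.5f}" for nt, b in zip(NUCLEOTIDES, background)))
    out.append("")
    for pwm in pwms:
        out.append(f"MOTIF {pwm.id}")
        out.append(f"letter-probability matrix: alength= 4 w= {pwm.length} nsites= 20 E= 0")
        for col in pwm.matrix.T:
            out.append(" ".join(f"{x:.6f}" for x in col))
        out.append("")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# FASTA promoters


def read_promoters(path: str | Path) -> dict[str, str]:
    """FASTA -> {gene id: uppercase sequence}; duplicate ids are an error."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise TrnkitError(f"duplicate promoter record id {rec.id}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_promoters(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=g, description="") for g, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Ontology and annotations

_KEEP_RELATIONS = ("is_a", "part_of")


def read_obo(path: str | Path) -> nx.DiGraph:
    """Read an OBO ontology; keep is_a/part_of edges (child -> parent)."""
    multi = obonet.read_obo(str(path))
    dag = nx.DiGraph()
    dag.add_nodes_from(multi.nodes(data=True))
    for child, parent, rel in multi.edges(keys=True):
        if rel in _KEEP_RELATIONS:
            dag.add_edge(child, parent, relation=rel)
    return dag


def write_obo(dag: nx.DiGraph, path: str | Path, ontology_name: str = "toy-bp") -> None:
    """Serialize a term DAG to OBO (enough for obonet to round-trip)."""
    out = ["format-version: 1.2", f"ontology: {ontology_name}", ""]
    for term in dag.nodes:
        out.append("[Term]")
        out.append(f"id: {term}")
        name = dag.nodes[term].get("name", term)
        out.append(f"name: {name}")
        for _, parent, data in dag.out_edges(term, data=True):
            rel = data.get("relation", "is_a")
            if rel == "is_a":
                out.append(f"is_a: {parent} ! {parent}")
            else:
                out.append(f"relationship: {rel} {parent} ! {parent}")
        out.append("")
    Path(path).write_text("\n".join(out))


def read_annotations(path: str | Path) -> dict[str, set[str]]:
    """Gene -> GO term annotations from GAF 2.x or two-column TSV.

    GAF input is filtered to the biological-process aspect (column 9 == "P").
    """
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("!gaf-version"):
        annotations: dict[str, set[str]] = {}
        with open(path) as fh:
            for rec in GOA.gafiterator(fh):
                if rec["Aspect"] != "P":
                    continue
                annotations.setdefault(rec["DB_Object_ID"], set()).add(rec["GO_ID"])
        return annotations
    df = pd.read_csv(path, sep="\t", header=None, comment="!", names=["gene", "term"])
    annotations = {}
    for gene, term in zip(df["gene"].astype(str), df["term"].astype(str)):
        annotations.setdefault(gene, set()).add(term)
    return annotations


def write_annotations(annotations: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(annotations):
            for term in sorted(annotations[gene]):
                fh.write(f"{gene}\t{term}\n")


def read_go_corpus(obo_path: str | Path, annotation_path: str | Path) -> GOCorpus:
    return GOCorpus(read_obo(obo_path), read_annotations(annotation_path))


# ---------------------------------------------------------------------------
# Networks


def write_network(net: RegulatoryNetwork, path: str | Path) -> None:
    """TSV edge list (tf, target, weight), lexicographically ordered."""
    edges = sorted(net.edges())
    if not edges:
        warn("writing an empty network (header only)")
    with open(path, "w") as fh:
        fh.write("tf\ttarget\tweight\n")
        for tf, target, w in edges:
            fh.write(f"{tf}\t{target}\t{w!r}\n")


def read_network(path: str | Path) -> RegulatoryNetwork:
    df = pd.read_csv(path, sep="\t", dtype={"tf": str, "target": str})
    return RegulatoryNetwork(
        (t, g, float(w)) for t, g, w in zip(df["tf"], df["target"], df["weight"])
    )


def write_graphml(net: RegulatoryNetwork, path: str | Path) -> None:
    nx.write_graphml(net.graph, str(path))


def read_gene_lengths(path: str | Path) -> pd.Series:
    """Gene lengths from a two-column TSV (gene_id, length) or GFF3.

    GFF3 input takes each ``gene`` feature's end - start + 1.
    """
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("##gff"):
        lengths: dict[str, int] = {}
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 9 or parts[2] != "gene":
                    continue
                attrs = dict(
                    kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
                )
                gid = attrs.get("ID") or attrs.get("gene_id")
                if gid:
                    lengths[gid] = int(parts[4]) - int(parts[3]) + 1
        return pd.Series(lengths, name="length")
    df = pd.read_csv(path, sep="\t")
    if "gene_id" in df.columns:
        return pd.Series(df["length"].to_numpy(), index=df["gene_id"].astype(str), name="length")
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "length"])
    return pd.Series(df["length"].to_numpy(), index=df["gene_id"].astype(str), name="length")


def write_gene_lengths(lengths: pd.Series, path: str | Path) -> None:
    lengths.rename("length").to_csv(path, sep="\t", index_label="gene_id")
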