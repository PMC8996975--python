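"""Readers and writers for the pipeline's plain-text carrier formats.

GMT (gene-set collections), CLS (two-class phenotype labels), TSV
expression matrices (first column = row id) and two-column probe
annotation tables.  All formats are line-oriented text so runs are
diff-able and language-neutral.
"""

from __future__ import annotations

import os

import pandas as pd

from .containers import ExpressionMatrix, GeneSet, GeneSetCollection, ProbeAnnotation

__all__ = [
    "read_gmt",
    "write_gmt",
    "read_cls",
    "write_cls",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_annotation_tsv",
    "write_annotation_tsv",
]


def read_gmt(path: str | os.PathLike) -> GeneSetCollection:
    """Parse a GMT file: one set per line, ``name<TAB>description<TAB>members...``.

    Duplicate member symbols within a set are dropped; a line with fewer
    than three tab-separated fields raises with its line number.
    """
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated fields, got {len(fields)}"
                )
            name, description, *members = fields
            members = [m for m in members if m]
            if not members:
                raise ValueError(f"{path}: line {lineno}: gene set {name!r} has no members")
            sets.append(GeneSet(name, description, tuple(members)))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *s.members]) + "\n")


def read_cls(path: str | os.PathLike) -> pd.Series:
    """Read a 3-line CLS phenotype file into per-sample labels.

    Line 1: ``<n_samples> <n_classes> 1``; line 2: ``# name1 name2``;
    line 3: space-separated per-sample labels (names or 0/1 indices).
    Exactly two classes are enforced.
    """
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if len(lines) < 3:
        raise ValueError(f"{path}: CLS file needs 3 non-empty lines, got {len(lines)}")
    header = lines[0].split()
    n_samples, n_classes = int(header[0]), int(header[1])
    if n_classes != 2:
        raise ValueError(f"{path}: pipeline requires exactly 2 phenotype classes, got {n_classes}")
    names_line = lines[1].split()
    if names_line[0].startswith("#"):
        names_line = names_line[1:] if names_line[0] == "#" else [names_line[0][1:], *names_line[1:]]
    class_names = names_line
    if len(class_names) != 2:
        raise ValueError(f"{path}: expected 2 class names, got {class_names}")
    tokens = lines[2].split()
    if len(tokens) != n_samples:
        raise ValueError(
            f"{path}: count line declares {n_samples} samples but label line has {len(tokens)}"
        )
    # tokens may be class names or numeric indices into the name list
    labels = []
    for t in tokens:
        if t in class_names:
            labels.append(t)
        elif t.isdigit() and int(t) < len(class_names):
            labels.append(class_names[int(t)])
        else:
            raise ValueError(f"{path}: unknown class token {t!r}")
    return pd.Series(labels, index=[f"s{i}" for i in range(len(labels))])


def write_cls(labels: pd.Series, path: str | os.PathLike) -> None:
    class_names = list(dict.fromkeys(labels))
    if len(class_names) != 2:
        raise ValueError(f"CLS requires exactly 2 classes, got {class_names}")
    with open(path, "w") as fh:
        fh.write(f"{len(labels)} 2 1\n")
        fh.write("# " + " ".join(class_names) + "\n")
        fh.write(" ".join(str(v) for v in labels) + "\n")


def read_matrix_tsv(
    path: str | os.PathLike,
    scale: str,
    phenotype: pd.Series,
    classes: tuple[str, str] | None = None,
) -> ExpressionMatrix:
    """Read a TSV expression matrix (rows = probes/genes, first column = id).

    The phenotype series is aligned positionally if its index does not
    match the matrix columns (the CLS format carries no sample names).
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    pheno = pd.Series(phenotype)
    if not set(df.columns).issubset(set(pheno.index)):
        if len(pheno) != df.shape[1]:
            raise ValueError(
                f"{path}: phenotype has {len(pheno)} labels for {df.shape[1]} samples"
            )
        pheno = pd.Series(pheno.to_numpy(), index=df.columns)
    return ExpressionMatrix(df, scale, pheno, classes)


def write_matrix_tsv(matrix: ExpressionMatrix, path: str | os.PathLike, comments: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for c in comments or []:
            fh.write(f"# {c}\n")
        matrix.values.rename_axis("id").to_csv(fh, sep="\t")


def read_annotation_tsv(path: str | os.PathLike) -> ProbeAnnotation:
    """Two-column TSV ``probe<TAB>gene_symbol``; header optional."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns")
            probe, gene = fields[0], fields[1]
            if lineno == 1 and probe.lower() in ("probe", "probe_id", "id"):
                continue
            if gene:
                if probe in mapping and mapping[probe] != gene:
                    raise ValueError(f"{path}: probe {probe!r} mapped to two symbols")
                mapping[probe] = gene
    return ProbeAnnotation(mapping)


def write_annotation_tsv(annot: ProbeAnnotation, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("probe_id\tgene_symbol\n")
        for probe, gene in annot.mapping.items():
            fh.write(f"{probe}\t{gene}\n")
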