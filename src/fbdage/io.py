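"""Readers and writers for the plain-text formats used by the pipeline.

* FASTA for molecular alignments (strict parser with line numbers).
* NEXUS ``CHARACTERS`` block with ``DATATYPE=STANDARD`` for morphology.
* Newick with branch lengths in Myr; sampled ancestors are encoded as
  zero-length terminal branches.
* Tab-separated tables: fossil age ranges (``taxon  min_age  max_age``),
  fossil truth (for assessment) and MCMC traces (leading ``state`` column,
  readable by standard trace viewers).
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .charsim import CharacterMatrix, DNA_SYMBOLS
from .trees import Tree, newick_string, parse_newick

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_nexus_standard",
    "write_nexus_standard",
    "read_newick",
    "write_newick",
    "read_age_ranges",
    "write_age_ranges",
    "read_trace",
    "write_trace",
]


class FormatError(ValueError):
    """Malformed input file; message includes the offending line number."""


def _open(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path) -> CharacterMatrix:
    rows: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with _open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    rows[name] = "".join(chunks)
                name = line[1:].strip()
                if not name:
                    raise FormatError(f"line {lineno}: empty FASTA header")
                if name in rows:
                    raise FormatError(f"line {lineno}: duplicate taxon {name!r}")
                chunks = []
            else:
                if name is None:
                    raise FormatError(f"line {lineno}: sequence before first header")
                bad = set(line.upper()) - set(DNA_SYMBOLS + "?-NX")
                if bad:
                    raise FormatError(
                        f"line {lineno}: invalid characters {sorted(bad)}"
                    )
                chunks.append(line.upper())
    if name is not None:
        rows[name] = "".join(chunks)
    if not rows:
        raise FormatError("empty FASTA file")
    lengths = {len(s) for s in rows.values()}
    if len(lengths) > 1:
        raise FormatError(f"unequal sequence lengths: {sorted(lengths)}")
    return CharacterMatrix.from_strings(rows, "dna")


def write_fasta(matrix: CharacterMatrix, path, width: int = 80) -> None:
    with _open(path, "wt") as fh:
        for taxon in matrix.taxa:
            fh.write(f">{taxon}\n")
            s = matrix.row_string(taxon)
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# NEXUS standard characters
# ---------------------------------------------------------------------------


def write_nexus_standard(matrix: CharacterMatrix, path) -> None:
    """One DATATYPE=STANDARD matrix with SYMBOLS covering the max state count."""
    max_states = int(np.max(matrix.state_counts))
    symbols = "".join(str(i) for i in range(max_states))
    pad = max(len(t) for t in matrix.taxa) + 2
    with _open(path, "wt") as fh:
        fh.write("#NEXUS\n\nBEGIN CHARACTERS;\n")
        fh.write(
            f"    DIMENSIONS NTAX={len(matrix.taxa)} NCHAR={matrix.n_char};\n"
        )
        fh.write(
            f'    FORMAT DATATYPE=STANDARD SYMBOLS="{symbols}" MISSING=? GAP=-;\n'
        )
        fh.write("    MATRIX\n")
        for taxon in matrix.taxa:
            fh.write(f"    {taxon.ljust(pad)}{matrix.row_string(taxon)}\n")
        fh.write("    ;\nEND;\n")
        # auxiliary block so state counts per character survive a round trip
        counts = " ".join(str(int(c)) for c in matrix.state_counts)
        fh.write(f"\n[STATECOUNTS {counts}]\n")


def read_nexus_standard(path) -> CharacterMatrix:
    """Parse a standard-data NEXUS matrix (unknown blocks are skipped)."""
    import dendropy

    text = Path(path).read_text()
    try:
        dmat = dendropy.StandardCharacterMatrix.get(data=text, schema="nexus")
    except Exception as exc:  # dendropy errors carry their own positions
        raise FormatError(f"NEXUS parse failure: {exc}") from exc
    rows = {}
    for taxon in dmat.taxon_namespace:
        seq = dmat[taxon]
        chars = []
        for cell in seq:
            s = str(cell)
            chars.append("?" if s in ("?", "-") else s)
        rows[taxon.label.replace(" ", "_")] = "".join(chars)
    state_counts = None
    if "[STATECOUNTS" in text:
        inner = text.split("[STATECOUNTS", 1)[1].split("]", 1)[0]
        state_counts = np.array([int(x) for x in inner.split()])
    return CharacterMatrix.from_strings(rows, "standard", state_counts=state_counts)


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------


def write_newick(tree: Tree, path, include_stem: bool = False) -> None:
    with _open(path, "wt") as fh:
        fh.write(newick_string(tree, include_stem=include_stem) + "\n")


def read_newick(path, origin_age: Optional[float] = None) -> Tree:
    with _open(path) as fh:
        text = fh.read()
    return parse_newick(text, origin_age=origin_age)


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------


def write_age_ranges(table, path) -> None:
    """``taxon  min_age  max_age`` (TSV); accepts a DataFrame or tuples."""
    if not isinstance(table, pd.DataFrame):
        table = pd.DataFrame(table, columns=["taxon", "min_age", "max_age"])
    bad = table[table["min_age"] > table["max_age"]]
    if len(bad):
        raise ValueError(f"min_age > max_age for {bad['taxon'].tolist()}")
    table.to_csv(path, sep="\t", index=False)


def read_age_ranges(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    expected = {"taxon", "min_age", "max_age"}
    if not expected <= set(df.columns):
        raise FormatError(
            f"age-range table must have columns {sorted(expected)}"
        )
    bad = df[df["min_age"] > df["max_age"]]
    if len(bad):
        raise FormatError(f"min_age > max_age for {bad['taxon'].tolist()}")
    return df


def write_trace(df: pd.DataFrame, path) -> None:
    cols = ["state"] + [c for c in df.columns if c != "state"]
    df[cols].to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_trace(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if "state" not in df.columns:
        raise FormatError("trace file lacks the leading 'state' column")
    return df


def write_tree_log(trees: list, path) -> None:
    with _open(path, "wt") as fh:
        for t in trees:
            fh.write(t.rstrip() + "\n")


def read_tree_log(path) -> list:
    out = []
    with _open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(parse_newick(line))
    return out
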