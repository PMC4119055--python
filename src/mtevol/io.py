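"""Readers and writers for the package's standard formats.

FASTA goes through Biopython; tables are TSVs whose comment headers carry
version, seed and parameter provenance.  The packaged bait manifest lists
the E. coli RNA MTase families used as scan queries (34 families, the
bifunctional RlmK/L entry counting as two) plus nine non-RNA MTase
families, and the pathogen panel lists the eight species of the pangenome
demonstration.
"""

from __future__ import annotations

import hashlib
import io as _io
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "BaitManifest",
    "load_bait_manifest",
    "load_pathogen_panel",
    "write_table",
    "read_table",
]

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYXBZUOJ")
NUCLEOTIDE_ALPHABET = frozenset("ACGTUN")
GAP_CHARS = frozenset("-.")

SUBSTRATES = frozenset({"16S rRNA", "23S rRNA", "tRNA", "tRNA/tmRNA", "non-RNA"})
CLASSES = frozenset({"Class I", "Class IV", "Radical SAM"})


def read_fasta(path, mode: str = "protein") -> list[tuple[str, str]]:
    """Read a FASTA file as (id, sequence) pairs.

    ``mode`` is ``protein``, ``nucleotide`` or ``aligned``; aligned mode
    enforces equal lengths, nucleotide mode validates the DNA/RNA alphabet,
    and duplicate ids are rejected in every mode.
    """
    if mode not in {"protein", "nucleotide", "aligned"}:
        raise ValueError(f"unknown mode {mode!r}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"empty or unreadable FASTA: {path}")
    seen = set()
    out = []
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        alphabet = NUCLEOTIDE_ALPHABET if mode == "nucleotide" else PROTEIN_ALPHABET
        allowed = alphabet | GAP_CHARS if mode != "nucleotide" else alphabet | GAP_CHARS
        bad = set(seq) - allowed
        if bad:
            raise ValueError(
                f"record {rec.id!r}: illegal characters {sorted(bad)} for mode {mode}"
            )
        out.append((rec.id, seq))
    if mode == "aligned":
        lengths = {len(s) for _, s in out}
        if len(lengths) != 1:
            offender = max(out, key=lambda r: len(r[1]))[0]
            raise ValueError(
                f"aligned mode requires equal lengths; offending record {offender!r}"
            )
    return out


def write_fasta(path, records: Iterable[tuple[str, str]], width: int = 70) -> None:
    recs = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


@dataclass
class BaitManifest:
    """Validated family manifest with substrate/class vocabularies."""

    frame: pd.DataFrame

    @property
    def families(self) -> list[str]:
        return self.frame["family"].tolist()

    @property
    def rna_family_count(self) -> int:
        """RNA MTase families, counting dual entries by their weight."""
        rna = self.frame[self.frame["substrate"] != "non-RNA"]
        return int(rna["counts_as"].sum())

    @property
    def non_rna_family_count(self) -> int:
        non = self.frame[self.frame["substrate"] == "non-RNA"]
        return int(non["counts_as"].sum())

    def counts_by_substrate(self) -> pd.Series:
        return self.frame.groupby("substrate")["counts_as"].sum().sort_index()

    def counts_by_class(self) -> pd.Series:
        return self.frame.groupby("mtase_class")["counts_as"].sum().sort_index()

    def function_labels(self) -> dict[str, str]:
        return dict(zip(self.frame["family"], self.frame["function"]))


def _packaged(name: str):
    return resources.files("mtevol").joinpath("data", name)


def load_bait_manifest(path=None) -> BaitManifest:
    """Load and validate a bait manifest TSV (packaged default)."""
    source = _packaged("bait_manifest.tsv") if path is None else Path(path)
    with (source.open() if hasattr(source, "open") else open(source)) as fh:
        frame = pd.read_csv(fh, sep="\t", comment="#")
    required = {
        "family",
        "alt_names",
        "substrate",
        "modification",
        "mtase_class",
        "accession",
        "counts_as",
        "function",
    }
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    dup = frame["family"][frame["family"].duplicated()].tolist()
    if dup:
        raise ValueError(f"duplicated family names: {dup}")
    bad_sub = set(frame["substrate"]) - SUBSTRATES
    if bad_sub:
        raise ValueError(f"unknown substrates: {sorted(bad_sub)}")
    bad_cls = set(frame["mtase_class"]) - CLASSES
    if bad_cls:
        raise ValueError(f"unknown MTase classes: {sorted(bad_cls)}")
    return BaitManifest(frame=frame)


def load_pathogen_panel(path=None) -> pd.DataFrame:
    """The eight-species pangenome panel (species, n_genomes)."""
    source = _packaged("pathogens.tsv") if path is None else Path(path)
    with (source.open() if hasattr(source, "open") else open(source)) as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def params_hash(params: Mapping) -> str:
    text = ";".join(f"{k}={params[k]}" for k in sorted(params))
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def write_table(
    path,
    frame: pd.DataFrame,
    seed: int | None = None,
    params: Mapping | None = None,
    note: str = "",
) -> None:
    """Write a TSV with a provenance comment header.

    The header records package version, seed, a short parameter hash and a
    free-text note; coordinates in all emitted tables are 1-based inclusive.
    """
    from mtevol import __version__

    buf = _io.StringIO()
    buf.write(f"# mtevol {__version__}\n")
    if seed is not None:
        buf.write(f"# seed: {seed}\n")
    if params:
        buf.write(f"# params: {params_hash(params)} "
                  + " ".join(f"{k}={params[k]}" for k in sorted(params)) + "\n")
    if note:
        buf.write(f"# {note}\n")
    buf.write("# coordinates: 1-based inclusive\n")
    frame.to_csv(buf, sep="\t", index=False)
    Path(path).write_text(buf.getvalue())


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
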