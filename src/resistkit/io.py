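"""Readers and writers for the pipeline's file formats.

Formats handled: protein FASTA (one file per strain), annotation-transfer
GFF3 carrying per-transcript liftover QC attributes, two-column contig-length
tables, dose--mortality bioassay TSVs, and the screen's report TSV.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .bioassay import DoseGroup
from .core import (
    ALPHABET,
    GAP,
    ContigContext,
    FormatError,
    ProteinRecord,
    StrainProteome,
    TransferAttributes,
    _ALPHABET_SET,
)
from .screen import MutationReport, MutationSite

__all__ = [
    "read_protein_fasta",
    "write_protein_fasta",
    "read_transfer_gff",
    "read_contig_lengths",
    "read_bioassay_table",
    "write_bioassay_table",
    "write_report_tsv",
    "read_report_tsv",
]


# ---------------------------------------------------------------------------
# FASTA


def read_protein_fasta(path: str | Path, strain: str) -> StrainProteome:
    """Read a per-strain protein FASTA into a :class:`StrainProteome`.

    The first whitespace-delimited header token is the transcript ID;
    optional ``gene=``/``cds_complete=`` key=value pairs may follow.
    A single terminal ``*`` (stop) is stripped; lowercase is uppercased.
    Duplicate IDs, empty sequences and out-of-alphabet characters are errors.
    """
    proteome = StrainProteome(strain=strain)
    for rec in SeqIO.parse(str(path), "fasta"):
        tid = rec.id
        gene_id = tid
        cds_complete = True
        for token in rec.description.split()[1:]:
            if token.startswith("gene="):
                gene_id = token[len("gene="):]
            elif token.startswith("cds_complete="):
                cds_complete = token[len("cds_complete="):].lower() == "true"
        seq = str(rec.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        if not seq:
            raise FormatError(f"{path}: record {tid!r} has an empty sequence")
        if "*" in seq:
            raise FormatError(f"{path}: record {tid!r} contains an internal '*'")
        bad = set(seq) - _ALPHABET_SET
        if bad:
            raise FormatError(
                f"{path}: record {tid!r} contains invalid character(s) {sorted(bad)!r} "
                f"(allowed: {ALPHABET})"
            )
        try:
            proteome.add(
                ProteinRecord(
                    transcript_id=tid,
                    gene_id=gene_id,
                    strain=strain,
                    sequence=seq,
                    cds_complete=cds_complete,
                )
            )
        except FormatError as exc:
            raise FormatError(f"{path}: {exc}") from None
    return proteome


def write_protein_fasta(proteome: StrainProteome, path: str | Path) -> None:
    """Write a proteome as FASTA; round-trips through :func:`read_protein_fasta`."""
    records = []
    for tid in proteome.ids():
        rec = proteome[tid]
        desc = f"gene={rec.gene_id} cds_complete={rec.cds_complete}"
        records.append(SeqRecord(Seq(rec.sequence), id=tid, description=desc))
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


# ---------------------------------------------------------------------------
# GFF3


def _parse_gff_attributes(raw: str) -> dict[str, str]:
    # Accept both "key=value" (GFF3) and the "key: value" dialect some
    # liftover tool versions print for QC flags.
    out: dict[str, str] = {}
    for chunk in raw.strip().rstrip(";").split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" in chunk:
            key, _, val = chunk.partition("=")
        elif ":" in chunk:
            key, _, val = chunk.partition(":")
        else:
            key, val = chunk, ""
        out[key.strip()] = val.strip()
    return out


def _truthy(value: str) -> bool:
    return value.strip().lower() in ("true", "1", "yes")


def read_transfer_gff(
    path: str | Path,
    contig_lengths: Optional[Mapping[str, int]] = None,
) -> tuple[list[TransferAttributes], dict[str, ContigContext]]:
    """Parse an annotation-transfer GFF3.

    Returns one :class:`TransferAttributes` per transcript (mRNA) feature and
    a transcript-ID-keyed map of :class:`ContigContext` built from gene
    feature coordinates. Contig lengths come from ``##sequence-region``
    pragmas or the ``contig_lengths`` mapping (the latter wins).

    ``matches_ref_protein`` defaults to ``True`` when absent; the attribute
    value ``False`` (case-insensitive, in either ``key=value`` or
    ``key: value`` style) maps to ``False``.
    """
    lengths: dict[str, int] = {}
    genes: dict[str, tuple[str, int, int, str]] = {}
    attrs: list[TransferAttributes] = []
    transcript_gene: dict[str, str] = {}

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    lengths[parts[1]] = int(parts[3])
                continue
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, got {len(cols)}"
                )
            contig, _source, ftype, start_s, end_s, _score, strand, _frame, raw_attrs = cols
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            a = _parse_gff_attributes(raw_attrs)
            if ftype == "gene":
                genes[a.get("ID", f"gene@{lineno}")] = (contig, start, end, strand)
            elif ftype in ("mRNA", "transcript"):
                tid = a.get("ID", f"mRNA@{lineno}")
                transcript_gene[tid] = a.get("Parent", tid)
                attrs.append(
                    TransferAttributes(
                        transcript_id=tid,
                        matches_ref_protein=not (
                            a.get("matches_ref_protein", "").strip().lower() == "false"
                        ),
                        missing_start=_truthy(a.get("missing_start_codon", "false")),
                        missing_stop=_truthy(a.get("missing_stop_codon", "false")),
                    )
                )

    if contig_lengths:
        lengths.update(contig_lengths)

    contexts: dict[str, ContigContext] = {}
    for tid, gid in transcript_gene.items():
        if gid not in genes:
            continue
        contig, start, end, strand = genes[gid]
        if contig not in lengths:
            continue  # no declared length: context unknown, not an error
        if end > lengths[contig]:
            raise FormatError(
                f"{path}: gene {gid!r} ends at {end} beyond contig "
                f"{contig!r} length {lengths[contig]}"
            )
        contexts[tid] = ContigContext(
            contig_id=contig,
            contig_length=lengths[contig],
            gene_start=start,
            gene_end=end,
            strand=strand,
        )
    return attrs, contexts


def read_contig_lengths(path: str | Path) -> dict[str, int]:
    """Read a two-column ``contig<TAB>length`` table."""
    df = pd.read_csv(path, sep="\t", header=None, names=["contig", "length"], comment="#")
    out = dict(zip(df["contig"].astype(str), df["length"].astype(int)))
    for contig, length in out.items():
        if length <= 0:
            raise FormatError(f"{path}: contig {contig!r} has non-positive length {length}")
    return out


# ---------------------------------------------------------------------------
# Bioassay tables


def read_bioassay_table(path: str | Path) -> tuple[list[DoseGroup], Optional[DoseGroup]]:
    """Read a ``dose / n / dead`` TSV into dose groups plus optional control.

    The row with ``dose == 0`` (at most one) is the solvent-only control.
    At least 3 non-control dose groups are required (the probit model has two
    parameters and needs residual degrees of freedom).
    """
    df = pd.read_csv(path, sep="\t")
    required = {"dose", "n", "dead"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: need columns {sorted(required)}, got {list(df.columns)}")
    groups: list[DoseGroup] = []
    control: Optional[DoseGroup] = None
    for _, row in df.iterrows():
        dose, n, dead = float(row["dose"]), int(row["n"]), int(row["dead"])
        if n <= 0:
            raise FormatError(f"{path}: non-positive n ({n}) at dose {dose}")
        if dead < 0 or dead > n:
            raise FormatError(f"{path}: dead ({dead}) outside 0..n ({n}) at dose {dose}")
        if dose == 0:
            if control is not None:
                raise FormatError(f"{path}: more than one control (dose=0) row")
            control = DoseGroup(dose=0.0, n=n, dead=dead, is_control=True)
        elif dose < 0:
            raise FormatError(f"{path}: negative dose {dose}")
        else:
            groups.append(DoseGroup(dose=dose, n=n, dead=dead))
    if len(groups) < 3:
        raise FormatError(
            f"{path}: need at least 3 non-control dose groups, got {len(groups)}"
        )
    return groups, control


def write_bioassay_table(
    groups: Sequence[DoseGroup], path: str | Path, control: Optional[DoseGroup] = None
) -> None:
    rows = [{"dose": g.dose, "n": g.n, "dead": g.dead} for g in groups]
    if control is not None:
        rows.append({"dose": 0.0, "n": control.n, "dead": control.dead})
    pd.DataFrame(rows, columns=["dose", "n", "dead"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Report TSV

_REPORT_COLUMNS = [
    "transcript_id",
    "gene_id",
    "n_sites",
    "sites",
    "artifact_flags",
    "included",
    "n_columns",
]


def _format_site(site: MutationSite) -> str:
    cols = str(site.start) if site.start == site.end else f"{site.start}-{site.end}"
    return f"{cols}:{site.susceptible}:{site.reference}:{site.resistant}"


def _parse_site(transcript_id: str, token: str) -> MutationSite:
    cols, sus, ref, res = token.split(":")
    if "-" in cols:
        start_s, end_s = cols.split("-")
        start, end = int(start_s), int(end_s)
    else:
        start = end = int(cols)
    kind = "indel" if GAP in (sus + ref + res) else "substitution"
    return MutationSite(
        transcript_id=transcript_id,
        start=start,
        end=end,
        kind=kind,
        susceptible=sus,
        resistant=res,
        reference=ref,
    )


def write_report_tsv(reports: Iterable[MutationReport], path: str | Path) -> None:
    """Write mutation reports as a deterministic, lossless TSV.

    Rows sorted by transcript ID; site tokens are
    ``column[-column]:sus:ref:res`` joined by semicolons.
    """
    rows = []
    for rep in sorted(reports, key=lambda r: r.transcript_id):
        rows.append(
            {
                "transcript_id": rep.transcript_id,
                "gene_id": rep.gene_id,
                "n_sites": rep.n_sites,
                "sites": ";".join(_format_site(s) for s in rep.sites),
                "artifact_flags": ",".join(sorted(rep.artifact_flags)),
                "included": rep.included,
                "n_columns": rep.n_columns,
            }
        )
    pd.DataFrame(rows, columns=_REPORT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_report_tsv(path: str | Path) -> list[MutationReport]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(_REPORT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing report columns {sorted(missing)}")
    reports = []
    for _, row in df.iterrows():
        tid = row["transcript_id"]
        sites = [_parse_site(tid, tok) for tok in row["sites"].split(";") if tok]
        flags = {f for f in row["artifact_flags"].split(",") if f}
        reports.append(
            MutationReport(
                transcript_id=tid,
                gene_id=row["gene_id"],
                sites=sites,
                artifact_flags=flags,
                included=row["included"] == "True",
                n_columns=int(row["n_columns"]),
            )
        )
    return reports
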