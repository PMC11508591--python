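"""Genome-wide screen for resistance-strain-specific protein mutations.

The screen compares, per transcript, three protein sequences — the
susceptible strain (anchor), the resistant strain, and the reference
annotation — and keeps transcripts where the resistant strain is the lone
dissenter at one or more alignment columns. Columns where the susceptible
strain or the reference dissent, or where all three differ (triallelic), are
classified but never counted as resistance-specific sites. Apparent
mutations caused by annotation-transfer truncations (gene models abutting a
contig end, lost start/stop codons) are filtered out.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

from .align import ScoringScheme, TripleAlignment, assign_reference_ortholog, build_triple, default_scheme
from .core import GAP, ContigContext, ProteinRecord, StrainProteome, TransferAttributes

__all__ = [
    "CALLS",
    "ColumnCall",
    "MutationSite",
    "MutationReport",
    "ScreenConfig",
    "find_mismatched_transcripts",
    "classify_columns",
    "collapse_sites",
    "filter_artifacts",
    "screen_transcripts",
    "site_count_histogram",
]

logger = logging.getLogger(__name__)

#: the exhaustive, mutually exclusive set of per-column calls
CALLS = (
    "conserved",
    "resistant_specific_sub",
    "resistant_specific_gap",
    "susceptible_specific",
    "reference_specific",
    "triallelic",
    "terminal_artifact",
    "unclassified",
)


@dataclass(frozen=True)
class ColumnCall:
    """Classification of one alignment column.

    ``residues`` is the (susceptible, resistant, reference) triple including
    gap characters.
    """

    column: int  # 1-based
    residues: tuple[str, str, str]
    call: str

    def __post_init__(self) -> None:
        if self.call not in CALLS:
            raise ValueError(f"unknown call {self.call!r}")


@dataclass(frozen=True)
class MutationSite:
    """One resistance-specific mutation event.

    A substitution spans exactly one column; an indel spans a maximal run of
    resistant-specific gap columns. Residue strings are the per-strain states
    over the spanned columns.
    """

    transcript_id: str
    start: int
    end: int
    kind: str  # "substitution" | "indel"
    susceptible: str
    resistant: str
    reference: str

    def __post_init__(self) -> None:
        if self.kind not in ("substitution", "indel"):
            raise ValueError(f"unknown site kind {self.kind!r}")
        if self.kind == "substitution" and self.start != self.end:
            raise ValueError("substitution sites span exactly one column")
        if self.start > self.end:
            raise ValueError("site start must be <= end")


@dataclass
class MutationReport:
    """Per-transcript summary of resistance-specific sites and artifact flags."""

    transcript_id: str
    gene_id: str
    sites: list[MutationSite] = field(default_factory=list)
    artifact_flags: set[str] = field(default_factory=set)
    included: bool = False
    n_columns: int = 0

    _FLAGS = frozenset({"missing_start", "missing_stop", "contig_end", "no_reference"})

    def __post_init__(self) -> None:
        bad = self.artifact_flags - self._FLAGS
        if bad:
            raise ValueError(f"unknown artifact flags {sorted(bad)}")

    @property
    def n_sites(self) -> int:
        return len(self.sites)


@dataclass(frozen=True)
class ScreenConfig:
    """Tunable screen behaviour.

    allow_two_way
        count resistant-specific calls even when no reference ortholog exists
        (default off: without the reference one cannot tell which lineage
        mutated).
    indel_counting
        "run" counts one site per maximal gap run; "per_column" counts every
        gap column separately.
    window_bp
        distance from a contig boundary within which a gene counts as
        potentially fragmented.
    ortholog
        "shared_id" maps transcripts to the reference by identical transcript
        ID (the liftover setting); "best_hit" searches all reference proteins
        for the best global-alignment score.
    """

    allow_two_way: bool = False
    indel_counting: str = "run"
    window_bp: int = 1000
    ortholog: str = "shared_id"
    min_ortholog_score: int = 0

    def __post_init__(self) -> None:
        if self.indel_counting not in ("run", "per_column"):
            raise ValueError("indel_counting must be 'run' or 'per_column'")
        if self.ortholog not in ("shared_id", "best_hit"):
            raise ValueError("ortholog must be 'shared_id' or 'best_hit'")
        if self.window_bp < 0:
            raise ValueError("window_bp must be non-negative")


def find_mismatched_transcripts(
    susceptible: StrainProteome,
    resistant: StrainProteome,
    attributes: Optional[Sequence[TransferAttributes]] = None,
) -> list[str]:
    """Transcripts whose coding sequence differs between the two strains.

    When annotation-transfer attributes are available they are authoritative
    (``matches_ref_protein=False``), mirroring the liftover QC entry point;
    otherwise plain string inequality of the shared proteins is used.
    Returns a sorted list. Raises if the proteomes share no IDs (strain
    mix-up guard).
    """
    shared = set(susceptible.records) & set(resistant.records)
    if not shared:
        raise ValueError("proteomes share no transcript IDs; check strain inputs")
    if attributes is not None:
        flagged = {a.transcript_id for a in attributes if not a.matches_ref_protein}
        return sorted(flagged & shared)
    return sorted(
        tid for tid in shared if susceptible[tid].sequence != resistant[tid].sequence
    )


def classify_columns(triple: TripleAlignment, allow_two_way: bool = False) -> list[ColumnCall]:
    """Assign exactly one call to every column of a triple alignment.

    Rules (susceptible s, resistant r, reference f):

    - any 'X' involved -> unclassified (unknown residues evidence nothing);
    - s == r == f (non-gap) -> conserved;
    - s == f, r differs -> resistant_specific_sub (r a residue) or
      resistant_specific_gap (r a gap, or s == f == gap with r a residue);
    - s (resp. f) the lone dissenter -> susceptible_specific
      (resp. reference_specific);
    - all three pairwise distinct -> triallelic.

    Without a reference row, would-be resistant-specific calls downgrade to
    unclassified unless ``allow_two_way``.
    """
    calls: list[ColumnCall] = []
    two_way = not triple.reference_present
    for idx, (s, r, f) in enumerate(
        zip(triple.susceptible, triple.resistant, triple.reference), start=1
    ):
        if two_way:
            f = s  # treat the anchor as its own reference, then downgrade below
        if "X" in (s, r, f):
            call = "unclassified"
        elif s == r == f:
            call = "conserved"
        elif s == f:  # resistant is the lone dissenter (gap states included)
            call = "resistant_specific_sub" if r != GAP else "resistant_specific_gap"
            if s == GAP:  # insertion in the resistant strain
                call = "resistant_specific_gap"
            if two_way and not allow_two_way:
                call = "unclassified"
        elif r == f:
            call = "susceptible_specific"
        elif s == r:
            call = "reference_specific"
        else:
            call = "triallelic"
        calls.append(ColumnCall(column=idx, residues=(s, r, triple.reference[idx - 1]), call=call))
    return calls


def collapse_sites(
    calls: Sequence[ColumnCall],
    transcript_id: str = "",
    indel_counting: str = "run",
) -> list[MutationSite]:
    """Collapse column calls into mutation sites.

    Each resistant-specific substitution column is one site; each maximal run
    of resistant-specific gap columns is one indel site (or one per column
    with ``indel_counting='per_column'``). All other calls yield no site.
    """
    sites: list[MutationSite] = []
    run: list[ColumnCall] = []

    def flush() -> None:
        if not run:
            return
        if indel_counting == "per_column":
            chunks = [[c] for c in run]
        else:
            chunks = [list(run)]
        for chunk in chunks:
            sites.append(
                MutationSite(
                    transcript_id=transcript_id,
                    start=chunk[0].column,
                    end=chunk[-1].column,
                    kind="indel",
                    susceptible="".join(c.residues[0] for c in chunk),
                    resistant="".join(c.residues[1] for c in chunk),
                    reference="".join(c.residues[2] for c in chunk),
                )
            )
        run.clear()

    for call in calls:
        if call.call == "resistant_specific_gap":
            run.append(call)
            continue
        flush()
        if call.call == "resistant_specific_sub":
            sites.append(
                MutationSite(
                    transcript_id=transcript_id,
                    start=call.column,
                    end=call.column,
                    kind="substitution",
                    susceptible=call.residues[0],
                    resistant=call.residues[1],
                    reference=call.residues[2],
                )
            )
    flush()
    return sites


def _terminal_runs(triple: TripleAlignment) -> tuple[tuple[int, int], tuple[int, int]]:
    """1-based column spans of the leading and trailing resistant-gap runs.

    A terminal truncation does not always align flush with the terminus:
    when the cut boundary coincidentally matches retained residues, the
    optimal alignment slides the gap run inward past those matches. The
    terminal run is therefore the maximal resistant-row gap run separated
    from its terminus only by fully conserved columns. Returns (0, -1) for
    an absent run."""
    sus, res, ref = triple.susceptible, triple.resistant, triple.reference
    n = len(res)

    def conserved(i: int) -> bool:
        if res[i] == GAP or sus[i] != res[i]:
            return False
        return (not triple.reference_present) or ref[i] == res[i]

    def run_from(indices) -> tuple[int, int]:
        it = iter(indices)
        for i in it:
            if conserved(i):
                continue
            if res[i] != GAP:
                return (0, -1)
            span = [i]
            for j in it:
                if res[j] == GAP:
                    span.append(j)
                else:
                    break
            return (min(span) + 1, max(span) + 1)
        return (0, -1)

    leading = run_from(range(n))
    trailing = run_from(range(n - 1, -1, -1))
    return leading, trailing


def filter_artifacts(
    report: MutationReport,
    record: ProteinRecord,
    context: Optional[ContigContext] = None,
    attributes: Optional[TransferAttributes] = None,
    window_bp: int = 1000,
    triple: Optional[TripleAlignment] = None,
) -> MutationReport:
    """Remove annotation-transfer truncation artifacts from a report.

    ``record`` is the resistant-strain protein. Flags set: ``missing_start``
    when it lacks a leading 'M' (or the transfer attributes say the start
    codon is missing), ``missing_stop`` from attributes / ``cds_complete``,
    and ``contig_end`` when the gene lies within ``window_bp`` of a contig
    boundary. When a missing-codon flag co-occurs with ``contig_end``, sites
    lying inside the corresponding terminal gap run of the resistant row are
    artifacts of fragmentation, not mutations, and are removed; internal
    sites survive. ``included`` is recomputed.
    """
    flags = set(report.artifact_flags)
    if attributes is not None:
        if attributes.missing_start:
            flags.add("missing_start")
        if attributes.missing_stop:
            flags.add("missing_stop")
    if not record.has_start:
        flags.add("missing_start")
    # cds_complete=False alone cannot say which codon is missing; attribute it
    # to the stop side only when the start is demonstrably present.
    if not record.cds_complete and record.has_start:
        flags.add("missing_stop")
    if context is not None and context.distance_to_edge() < window_bp:
        flags.add("contig_end")

    sites = list(report.sites)
    if triple is not None and "contig_end" in flags:
        leading, trailing = _terminal_runs(triple)
        kept = []
        for site in sites:
            in_leading = (
                "missing_start" in flags
                and leading[0] <= site.start and site.end <= leading[1]
            )
            in_trailing = (
                "missing_stop" in flags
                and trailing[0] <= site.start and site.end <= trailing[1]
            )
            if not (in_leading or in_trailing):
                kept.append(site)
        sites = kept

    included = bool(sites) and "no_reference" not in flags
    return MutationReport(
        transcript_id=report.transcript_id,
        gene_id=report.gene_id,
        sites=sites,
        artifact_flags=flags,
        included=included,
        n_columns=report.n_columns,
    )


def screen_transcripts(
    susceptible: StrainProteome,
    resistant: StrainProteome,
    reference: StrainProteome,
    attributes: Optional[Sequence[TransferAttributes]] = None,
    contexts: Optional[Mapping[str, ContigContext]] = None,
    scheme: Optional[ScoringScheme] = None,
    config: Optional[ScreenConfig] = None,
    ortholog_map: Optional[Mapping[str, str]] = None,
) -> list[MutationReport]:
    """End-to-end screen: one report per mismatched transcript.

    Pipeline: find mismatched transcripts -> assign reference ortholog
    (explicit map, shared ID, or best-hit search) -> build triple alignment
    -> classify columns -> collapse sites -> filter artifacts. Reports with
    ``included=True`` form the resistance-specific set. Deterministic.
    """
    scheme = scheme or default_scheme()
    config = config or ScreenConfig()
    attr_by_id = {a.transcript_id: a for a in attributes} if attributes else {}
    contexts = contexts or {}

    mismatched = find_mismatched_transcripts(susceptible, resistant, attributes)
    logger.info("stage=mismatched count=%d", len(mismatched))

    reports: list[MutationReport] = []
    n_orthologed = 0
    for tid in mismatched:
        sus_rec = susceptible[tid]
        res_rec = resistant[tid]
        if ortholog_map is not None:
            ref_id = ortholog_map.get(tid)
        elif config.ortholog == "shared_id":
            ref_id = tid if tid in reference else None
        else:
            ref_id = assign_reference_ortholog(
                sus_rec, reference, scheme, min_score=config.min_ortholog_score
            )
        ref_seq = reference[ref_id].sequence if ref_id is not None else None
        if ref_id is not None:
            n_orthologed += 1

        triple = build_triple(
            sus_rec.sequence, res_rec.sequence, ref_seq, scheme, transcript_id=tid
        )
        calls = classify_columns(triple, allow_two_way=config.allow_two_way)
        sites = collapse_sites(calls, transcript_id=tid, indel_counting=config.indel_counting)
        report = MutationReport(
            transcript_id=tid,
            gene_id=sus_rec.gene_id,
            sites=sites,
            artifact_flags=set() if ref_id is not None else {"no_reference"},
            included=False,
            n_columns=triple.n_columns,
        )
        report = filter_artifacts(
            report,
            res_rec,
            context=contexts.get(tid),
            attributes=attr_by_id.get(tid),
            window_bp=config.window_bp,
            triple=triple,
        )
        reports.append(report)

    n_included = sum(1 for r in reports if r.included)
    logger.info(
        "stage=orthologed count=%d | stage=included count=%d", n_orthologed, n_included
    )
    return reports


def site_count_histogram(reports: Iterable[MutationReport]) -> dict[int, int]:
    """Site-count histogram over *included* reports: n_sites -> transcripts."""
    hist: dict[int, int] = {}
    for rep in reports:
        if rep.included:
            hist[rep.n_sites] = hist.get(rep.n_sites, 0) + 1
    return dict(sorted(hist.items()))
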