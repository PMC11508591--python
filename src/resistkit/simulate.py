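"""Synthetic data with ground truth for every pipeline stage.

Two generators: (1) strain-proteome triples (susceptible / resistant /
reference) derived from a common ancestral proteome with planted, labelled
mutation classes and optional annotation-transfer truncation artifacts;
(2) binomial dose--mortality bioassays under a probit model on log10 dose
with optional control mortality.

Everything is deterministic given its seed. Planted sites carry enough truth
to verify the screen's sensitivity and specificity exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .bioassay import DoseGroup
from .core import (
    AMINO_ACIDS,
    ContigContext,
    ProteinRecord,
    StrainProteome,
    TransferAttributes,
)

__all__ = [
    "SITE_CLASSES",
    "PlantedSite",
    "TruncationArtifact",
    "SyntheticTruth",
    "BioassayScenario",
    "generate_ancestral_proteome",
    "plant_mutations",
    "apply_truncation_artifacts",
    "simulate_bioassay",
    "genome_screen_fixture",
]

SITE_CLASSES = (
    "resistant_specific_sub",
    "resistant_specific_indel",
    "susceptible_specific",
    "reference_specific",
    "triallelic",
)

#: classes whose presence makes a transcript resistance-specific
RESISTANT_CLASSES = frozenset({"resistant_specific_sub", "resistant_specific_indel"})

#: classes that make susceptible and resistant proteins differ at all
MISMATCH_CLASSES = frozenset(
    {"resistant_specific_sub", "resistant_specific_indel", "susceptible_specific", "triallelic"}
)


@dataclass(frozen=True)
class PlantedSite:
    """Ground-truth record of one planted mutation (ancestral coordinates)."""

    transcript_id: str
    column: int  # 1-based position in the ancestral sequence
    site_class: str
    detail: str = ""

    def __post_init__(self) -> None:
        if self.site_class not in SITE_CLASSES:
            raise ValueError(f"unknown site class {self.site_class!r}")
        if self.column < 2:
            raise ValueError("planted sites never touch position 1")


@dataclass(frozen=True)
class TruncationArtifact:
    """One annotation-transfer truncation: which terminus, how many residues,
    and how close the gene sits to its contig end."""

    transcript_id: str
    side: str  # "prefix" | "suffix"
    cut: int
    edge_distance_bp: int


@dataclass
class SyntheticTruth:
    """Everything the generators planted, for exact downstream verification."""

    sites: list[PlantedSite] = field(default_factory=list)
    truncated: dict[str, TruncationArtifact] = field(default_factory=dict)
    contexts: dict[str, ContigContext] = field(default_factory=dict)
    attributes: list[TransferAttributes] = field(default_factory=list)

    def transcripts_with_class(self, classes: frozenset[str] | set[str]) -> set[str]:
        return {s.transcript_id for s in self.sites if s.site_class in classes}

    def resistant_transcripts(self) -> set[str]:
        """Transcripts that carry at least one resistance-specific site."""
        return self.transcripts_with_class(RESISTANT_CLASSES)

    def class_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for s in self.sites:
            out[s.site_class] = out.get(s.site_class, 0) + 1
        return out


def generate_ancestral_proteome(
    n_transcripts: int,
    length_range: tuple[int, int] = (30, 60),
    seed: int = 0,
) -> StrainProteome:
    """Random ancestral proteome: uniform residues, position 1 fixed to 'M'.

    IDs are ``gK.t1`` for K = 1..n. Deterministic given the seed.
    """
    lo, hi = length_range
    if lo > hi:
        raise ValueError(f"length_range inverted: {length_range}")
    if lo < 30:
        raise ValueError("minimum sequence length is 30")
    rng = np.random.default_rng(seed)
    proteome = StrainProteome(strain="susceptible")
    aa = np.array(list(AMINO_ACIDS))
    for k in range(1, n_transcripts + 1):
        length = int(rng.integers(lo, hi + 1))
        seq = "M" + "".join(rng.choice(aa, size=length - 1))
        proteome.add(
            ProteinRecord(
                transcript_id=f"g{k}.t1",
                gene_id=f"g{k}",
                strain="susceptible",
                sequence=seq,
            )
        )
    return proteome


def _other_residue(rng: np.random.Generator, *exclude: str) -> str:
    choices = [a for a in AMINO_ACIDS if a not in exclude]
    return choices[int(rng.integers(len(choices)))]


@dataclass
class _Edit:
    position: int  # 1-based ancestral position (insertion: insert after it)
    kind: str  # "sub" | "del" | "ins"
    strain: str  # which derived proteome the edit applies to
    payload: str  # replacement residue(s) / inserted residues; del: length as str


def _apply_edits(seq: str, edits: list[_Edit], strain: str) -> str:
    chars = list(seq)
    for edit in sorted((e for e in edits if e.strain == strain),
                       key=lambda e: e.position, reverse=True):
        i = edit.position - 1
        if edit.kind == "sub":
            chars[i] = edit.payload
        elif edit.kind == "del":
            del chars[i : i + int(edit.payload)]
        elif edit.kind == "ins":
            chars[i + 1 : i + 1] = list(edit.payload)
    return "".join(chars)


def plant_mutations(
    ancestral: StrainProteome,
    class_counts: dict[str, int],
    seed: int = 0,
    end_margin: int = 5,
    indel_len_range: tuple[int, int] = (1, 5),
) -> tuple[StrainProteome, StrainProteome, StrainProteome, SyntheticTruth]:
    """Derive susceptible / resistant / reference proteomes with planted sites.

    Each requested site is placed on a random transcript at a random interior
    position, never at position 1, never within ``end_margin`` residues of
    either terminus, and never overlapping (or directly abutting) another
    planted site — so every planted event is an unambiguous, isolated
    alignment feature. Deterministic given the seed.
    """
    unknown = set(class_counts) - set(SITE_CLASSES)
    if unknown:
        raise ValueError(f"unknown site classes {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    ids = ancestral.ids()
    used: dict[str, set[int]] = {tid: set() for tid in ids}
    edits: dict[str, list[_Edit]] = {tid: [] for tid in ids}
    truth = SyntheticTruth()

    def reserve(tid: str, lo: int, hi: int) -> bool:
        span = set(range(lo, hi + 1))
        if span & used[tid]:
            return False
        used[tid] |= span
        return True

    def place(footprint: int) -> tuple[str, int]:
        # returns (transcript, 1-based start position); buffer of 1 on each side
        if not ids:
            raise ValueError("class_counts exceed planting capacity of the proteome")
        for _ in range(10000):
            tid = ids[int(rng.integers(len(ids)))]
            L = len(ancestral[tid].sequence)
            lo = end_margin + 1
            hi = L - end_margin - footprint + 1
            if hi < lo:
                continue
            p = int(rng.integers(lo, hi + 1))
            if reserve(tid, p - 1, p + footprint):
                return tid, p
        raise ValueError("class_counts exceed planting capacity of the proteome")

    for site_class in SITE_CLASSES:  # fixed order for determinism
        for _ in range(class_counts.get(site_class, 0)):
            if site_class == "resistant_specific_indel":
                length = int(rng.integers(indel_len_range[0], indel_len_range[1] + 1))
                if rng.random() < 0.5:  # deletion from the resistant strain
                    tid, p = place(length)
                    removed = ancestral[tid].sequence[p - 1 : p - 1 + length]
                    edits[tid].append(_Edit(p, "del", "resistant", str(length)))
                    detail = f"del:{removed}"
                else:  # insertion into the resistant strain
                    tid, p = place(1)
                    inserted = "".join(
                        _other_residue(rng) for _ in range(length)
                    )
                    edits[tid].append(_Edit(p, "ins", "resistant", inserted))
                    detail = f"ins:{inserted}"
                truth.sites.append(
                    PlantedSite(tid, p, "resistant_specific_indel", detail)
                )
            else:
                tid, p = place(1)
                anc = ancestral[tid].sequence[p - 1]
                if site_class == "resistant_specific_sub":
                    new = _other_residue(rng, anc)
                    edits[tid].append(_Edit(p, "sub", "resistant", new))
                    detail = f"{anc}>{new}"
                elif site_class == "susceptible_specific":
                    new = _other_residue(rng, anc)
                    edits[tid].append(_Edit(p, "sub", "susceptible", new))
                    detail = f"{anc}>{new}"
                elif site_class == "reference_specific":
                    new = _other_residue(rng, anc)
                    edits[tid].append(_Edit(p, "sub", "reference", new))
                    detail = f"{anc}>{new}"
                else:  # triallelic: susceptible keeps ancestral, others differ
                    r1 = _other_residue(rng, anc)
                    r2 = _other_residue(rng, anc, r1)
                    edits[tid].append(_Edit(p, "sub", "resistant", r1))
                    edits[tid].append(_Edit(p, "sub", "reference", r2))
                    detail = f"{anc}>{r1}/{r2}"
                truth.sites.append(PlantedSite(tid, p, site_class, detail))

    proteomes = {}
    for strain in ("susceptible", "resistant", "reference"):
        proteome = StrainProteome(strain=strain)
        for tid in ids:
            rec = ancestral[tid]
            seq = _apply_edits(rec.sequence, edits[tid], strain)
            proteome.add(
                ProteinRecord(
                    transcript_id=tid,
                    gene_id=rec.gene_id,
                    strain=strain,
                    sequence=seq,
                    cds_complete=rec.cds_complete,
                )
            )
        proteomes[strain] = proteome
    return (
        proteomes["susceptible"],
        proteomes["resistant"],
        proteomes["reference"],
        truth,
    )


def apply_truncation_artifacts(
    proteome: StrainProteome,
    fraction: float,
    max_cut: int = 5,
    seed: int = 0,
    contig_length: int = 1_000_000,
    edge_window_bp: int = 500,
) -> tuple[StrainProteome, SyntheticTruth]:
    """Truncate a random subset of records at one terminus, emulating gene
    models broken by contig fragmentation during annotation transfer.

    A prefix cut removes 1..max_cut leading residues (losing the start
    codon); a suffix cut removes trailing residues (clearing
    ``cds_complete``). Truth carries, per truncated transcript, a matching
    :class:`ContigContext` placing the gene within ``edge_window_bp`` of a
    contig end, plus transfer attributes with the corresponding missing-codon
    flag.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must be in [0, 1]")
    min_len = min((len(proteome[t].sequence) for t in proteome), default=max_cut + 1)
    if max_cut >= min_len:
        raise ValueError("max_cut must be smaller than the shortest sequence")
    rng = np.random.default_rng(seed)
    ids = proteome.ids()
    n_cut = int(round(fraction * len(ids)))
    chosen = sorted(rng.choice(ids, size=n_cut, replace=False)) if n_cut else []

    out = StrainProteome(strain=proteome.strain)
    truth = SyntheticTruth()
    for tid in ids:
        rec = proteome[tid]
        if tid not in chosen:
            out.add(rec)
            continue
        cut = int(rng.integers(1, max_cut + 1))
        side = "prefix" if rng.random() < 0.5 else "suffix"
        dist = int(rng.integers(0, edge_window_bp))
        gene_bp = 3 * len(rec.sequence) + 3
        if side == "prefix":
            seq = rec.sequence[cut:]
            start = dist + 1
            ctx = ContigContext(
                contig_id=f"ctg_{tid}",
                contig_length=contig_length,
                gene_start=start,
                gene_end=start + gene_bp - 1,
            )
            missing_start, missing_stop = True, False
        else:
            seq = rec.sequence[:-cut]
            end = contig_length - dist
            ctx = ContigContext(
                contig_id=f"ctg_{tid}",
                contig_length=contig_length,
                gene_start=end - gene_bp + 1,
                gene_end=end,
            )
            missing_start, missing_stop = False, True
        out.add(rec.with_sequence(seq, cds_complete=False))
        truth.truncated[tid] = TruncationArtifact(
            transcript_id=tid, side=side, cut=cut, edge_distance_bp=dist
        )
        truth.contexts[tid] = ctx
        truth.attributes.append(
            TransferAttributes(
                transcript_id=tid,
                matches_ref_protein=False,
                missing_start=missing_start,
                missing_stop=missing_stop,
            )
        )
    return out, truth


# ---------------------------------------------------------------------------
# Bioassay simulation


@dataclass(frozen=True)
class BioassayScenario:
    """True dose--response parameters for a simulated bioassay.

    ``slope`` is the probit slope per log10 dose; ``control_mortality`` is
    the solvent-only death rate, entering the response as
    ``p(d) = c + (1 - c) * Phi(slope * (log10 d - log10 ld50))`` — the same
    scale the Abbott correction inverts.
    """

    ld50: float
    slope: float
    doses: tuple[float, ...]
    n_per_dose: int = 20
    control_mortality: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ld50 <= 0 or self.slope <= 0:
            raise ValueError("ld50 and slope must be positive")
        if any(d <= 0 for d in self.doses):
            raise ValueError("doses must be positive")
        if any(b <= a for a, b in zip(self.doses, self.doses[1:])):
            raise ValueError("doses must be strictly increasing")
        if self.n_per_dose <= 0:
            raise ValueError("n_per_dose must be positive")
        if not (0.0 <= self.control_mortality < 1.0):
            raise ValueError("control_mortality must be in [0, 1)")

    def expected_mortality(self, dose: float) -> float:
        c = self.control_mortality
        z = self.slope * (np.log10(dose) - np.log10(self.ld50))
        return float(c + (1.0 - c) * stats.norm.cdf(z))


def simulate_bioassay(
    scenario: BioassayScenario,
) -> tuple[list[DoseGroup], DoseGroup]:
    """Draw binomial dose groups plus a control group from the scenario."""
    rng = np.random.default_rng(scenario.seed)
    groups = []
    for dose in scenario.doses:
        p = scenario.expected_mortality(dose)
        dead = int(rng.binomial(scenario.n_per_dose, p))
        groups.append(DoseGroup(dose=dose, n=scenario.n_per_dose, dead=dead))
    control_dead = int(rng.binomial(scenario.n_per_dose, scenario.control_mortality))
    control = DoseGroup(dose=0.0, n=scenario.n_per_dose, dead=control_dead, is_control=True)
    return groups, control


# ---------------------------------------------------------------------------
# Genome-shaped screening fixture


def genome_screen_fixture(
    seed: int = 0,
    n_background: int = 562,
    n_mismatched: int = 3938,
    n_resistant: int = 729,
    n_single_site: int = 496,
    max_sites: int = 54,
    length_range: tuple[int, int] = (40, 60),
) -> tuple[StrainProteome, StrainProteome, StrainProteome, SyntheticTruth]:
    """Genome-shaped planted fixture: exact per-transcript site counts.

    Plants only substitutions, so site counts survive alignment exactly:
    ``n_resistant`` transcripts carry resistance-specific substitutions
    (``n_single_site`` with exactly one, one with ``max_sites``, the rest
    with 2..10 cycling); the other mismatched transcripts carry
    susceptible-specific or triallelic substitutions only; ``n_background``
    transcripts are untouched.
    """
    n_multi = n_resistant - n_single_site - 1
    if n_multi < 0:
        raise ValueError("n_single_site + 1 must not exceed n_resistant")
    if n_mismatched < n_resistant:
        raise ValueError("n_mismatched must be >= n_resistant")
    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))

    site_counts = [max_sites] + [1] * n_single_site + [
        2 + (i % 9) for i in range(n_multi)
    ]
    n_other = n_mismatched - n_resistant
    total = n_mismatched + n_background

    sus = StrainProteome(strain="susceptible")
    res = StrainProteome(strain="resistant")
    ref = StrainProteome(strain="reference")
    truth = SyntheticTruth()
    end_margin = 5

    for k in range(1, total + 1):
        tid, gid = f"g{k}.t1", f"g{k}"
        idx = k - 1
        want = site_counts[idx] if idx < len(site_counts) else 0
        length = int(rng.integers(*length_range, endpoint=True))
        length = max(length, 2 * end_margin + 3 * max(want, 1))
        seq = "M" + "".join(rng.choice(aa, size=length - 1))
        sus_seq = res_seq = ref_seq = seq

        if idx < len(site_counts):  # resistance-specific transcript
            positions = sorted(
                int(p)
                for p in rng.choice(
                    np.arange(end_margin + 1, length - end_margin + 1),
                    size=want,
                    replace=False,
                )
            )
            chars = list(seq)
            for p in positions:
                new = _other_residue(rng, chars[p - 1])
                truth.sites.append(
                    PlantedSite(tid, p, "resistant_specific_sub", f"{chars[p-1]}>{new}")
                )
                chars[p - 1] = new
            res_seq = "".join(chars)
        elif idx < n_resistant + n_other:  # mismatched but not resistance-specific
            p = int(rng.integers(end_margin + 1, length - end_margin + 1))
            anc = seq[p - 1]
            if rng.random() < 0.8:
                new = _other_residue(rng, anc)
                sus_seq = seq[: p - 1] + new + seq[p:]
                truth.sites.append(
                    PlantedSite(tid, p, "susceptible_specific", f"{anc}>{new}")
                )
            else:
                r1 = _other_residue(rng, anc)
                r2 = _other_residue(rng, anc, r1)
                res_seq = seq[: p - 1] + r1 + seq[p:]
                ref_seq = seq[: p - 1] + r2 + seq[p:]
                truth.sites.append(
                    PlantedSite(tid, p, "triallelic", f"{anc}>{r1}/{r2}")
                )

        sus.add(ProteinRecord(tid, gid, "susceptible", sus_seq))
        res.add(ProteinRecord(tid, gid, "resistant", res_seq))
        ref.add(ProteinRecord(tid, gid, "reference", ref_seq))
    return sus, res, ref, truth
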