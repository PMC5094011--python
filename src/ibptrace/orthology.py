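"""Orthology calling and completeness assessment.

Turns profile-HMM hits into presence/absence calls with the best
reciprocal hit (RBH) criterion: a candidate transcript is accepted as an
ortholog of a claimed gene only if its best-scoring entry across the
pooled reference proteomes carries that gene's label.  Copy counts
collapse mutually redundant transcripts (≥ 97 % local-alignment identity
over the shorter sequence by default).  Completeness is assessed
BUSCO-style against a set of conserved single-copy gene profiles, each
classified complete / fragmented / missing by profile coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence as TypingSequence

import numpy as np
import pandas as pd

from .phmm import EvalueCalibration, HmmHit, ProfileHMM, search
from .seqcore import (AA, NT, Msa, ScoringScheme, Sequence, SequenceError,
                      local_align, percent_identity, translate_six_frames)


class OrthologyError(ValueError):
    pass


@dataclass
class ReferenceProteome:
    """Labelled reference entries for one species: (sequence, gene label)."""

    species: str
    entries: list[tuple[Sequence, str]]


@dataclass
class OrthologyCall:
    species: str
    gene: str
    status: str                    # 'present' | 'absent'
    copy_count: int
    transcript_ids: list[str] = field(default_factory=list)
    rbh_partner: str | None = None

    def __post_init__(self) -> None:
        if self.status == "present" and (self.copy_count < 1 or not self.rbh_partner):
            raise OrthologyError("present call needs copies and an RBH partner")
        if self.status == "absent" and self.copy_count != 0:
            raise OrthologyError("absent call must have zero copies")


@dataclass
class PresenceMatrix:
    species: list[str]
    genes: list[str]
    calls: dict[tuple[str, str], OrthologyCall]

    def to_frame(self) -> pd.DataFrame:
        data = {g: [self.calls[(s, g)].copy_count for s in self.species]
                for g in self.genes}
        return pd.DataFrame(data, index=self.species)

    def binary(self) -> pd.DataFrame:
        return (self.to_frame() > 0).astype(int)

    def to_tsv(self) -> str:
        return self.to_frame().to_csv(sep="\t", index_label="species")

    def to_nexus(self) -> str:
        """Binary character block readable by the ancestral-state stage."""
        b = self.binary()
        lines = ["#NEXUS", "BEGIN DATA;",
                 f"DIMENSIONS NTAX={len(self.species)} NCHAR={len(self.genes)};",
                 'FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=?;',
                 "MATRIX"]
        for s in self.species:
            lines.append(f"  {s} {''.join(str(v) for v in b.loc[s])}")
        lines += [";", "END;", ""]
        return "\n".join(lines)


def read_nexus_matrix(text: str) -> pd.DataFrame:
    """Read the binary character block written by :meth:`PresenceMatrix.to_nexus`."""
    rows, in_matrix = {}, False
    for line in text.splitlines():
        t = line.strip()
        if t.upper() == "MATRIX":
            in_matrix = True
            continue
        if in_matrix:
            if t == ";" or t.upper().startswith("END"):
                break
            if t:
                name, states = t.split()
                rows[name] = [int(c) for c in states]
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# Reciprocal best hit
# ---------------------------------------------------------------------------

def reciprocal_best_hit(candidate: Sequence, claimed_gene: str,
                        references: TypingSequence[ReferenceProteome],
                        scheme: ScoringScheme | None = None
                        ) -> tuple[bool, str | None]:
    """Best reciprocal hit criterion against pooled reference proteomes.

    True iff the single best-scoring reference entry across all proteomes
    (ties broken by reference order, then lexicographic entry id) carries
    the claimed gene label.
    """
    if not references:
        raise OrthologyError("no reference proteomes")
    if len(candidate) == 0:
        raise OrthologyError("empty candidate sequence")
    scheme = scheme or ScoringScheme()
    best: tuple[float, int, str, str] | None = None
    for ri, ref in enumerate(references):
        for entry, gene in ref.entries:
            score, _ = local_align(candidate, entry, scheme)
            key = (-score, ri, entry.id)
            if best is None or key < (-best[0], best[1], best[2]):
                best = (score, ri, entry.id, gene)
    assert best is not None
    return best[3] == claimed_gene, best[2]


def _candidate_protein(transcript: Sequence, hit: HmmHit) -> Sequence:
    """Reciprocal-search query: the full stop-free stretch (ORF) of the
    hit's reading frame containing the envelope, not just the domain
    envelope itself — the surrounding protein context is what lets the
    reference search distinguish a gene from a shared-domain paralog."""
    if transcript.alphabet == AA:
        residues = transcript.residues
    else:
        frames = {f.frame: f for f in translate_six_frames(transcript)}
        residues = frames[hit.frame].residues
    start = hit.env_start
    end = hit.env_end
    while start > 0 and residues[start - 1] != "*":
        start -= 1
    while end < len(residues) and residues[end] != "*":
        end += 1
    return Sequence(transcript.id, residues[start:end], AA)


def call_gene(assembly: TypingSequence[Sequence], gene: str,
              profile: ProfileHMM, calibration: EvalueCalibration,
              references: TypingSequence[ReferenceProteome],
              e_threshold: float = 1e-14,
              scheme: ScoringScheme | None = None,
              redundancy_identity: float = 97.0,
              species: str = "?") -> OrthologyCall:
    """Presence call for one gene in one assembly.

    Present iff at least one transcript passes the E-value threshold and
    the RBH criterion; the copy count collapses transcripts that are
    mutually redundant at ``redundancy_identity`` % local identity over
    the shorter sequence.
    """
    if not assembly:
        return OrthologyCall(species=species, gene=gene, status="absent", copy_count=0)
    scheme = scheme or ScoringScheme()
    hits = search(profile, calibration, assembly, e_threshold=e_threshold)
    by_id = {t.id: t for t in assembly}
    accepted: list[tuple[Sequence, str]] = []
    for h in hits:
        cand = _candidate_protein(by_id[h.target_id], h)
        if len(cand) == 0:
            continue
        ok, partner = reciprocal_best_hit(cand, gene, references, scheme)
        if ok:
            accepted.append((cand, partner))
    if not accepted:
        return OrthologyCall(species=species, gene=gene, status="absent", copy_count=0)
    kept: list[tuple[Sequence, str]] = []
    for cand, partner in accepted:
        redundant = any(
            percent_identity(cand, prev, scheme) >= redundancy_identity
            for prev, _ in kept)
        if not redundant:
            kept.append((cand, partner))
    return OrthologyCall(species=species, gene=gene, status="present",
                         copy_count=len(kept),
                         transcript_ids=[c.id for c, _ in kept],
                         rbh_partner=kept[0][1])


def build_matrix(assemblies: dict[str, TypingSequence[Sequence]],
                 genes: TypingSequence[str],
                 profiles: dict[str, ProfileHMM],
                 calibrations: dict[str, EvalueCalibration],
                 references: TypingSequence[ReferenceProteome],
                 e_threshold: float = 1e-14,
                 scheme: ScoringScheme | None = None) -> PresenceMatrix:
    """One orthology call per (species, gene); deterministic given inputs."""
    species = list(assemblies)
    if len(set(species)) != len(species):
        raise OrthologyError("duplicate species ids")
    calls = {}
    for sp in species:
        for g in genes:
            calls[(sp, g)] = call_gene(assemblies[sp], g, profiles[g],
                                       calibrations[g], references,
                                       e_threshold=e_threshold, scheme=scheme,
                                       species=sp)
    return PresenceMatrix(species=species, genes=list(genes), calls=calls)


# ---------------------------------------------------------------------------
# Completeness assessment
# ---------------------------------------------------------------------------

@dataclass
class CompletenessRow:
    species: str
    complete: float      # percentages
    fragmented: float
    missing: float

    def __post_init__(self) -> None:
        total = self.complete + self.fragmented + self.missing
        if abs(total - 100.0) > 0.1:
            raise OrthologyError(f"completeness fractions sum to {total}, not 100")


def assess_completeness(assembly: TypingSequence[Sequence],
                        reference_set: TypingSequence[tuple[ProfileHMM, EvalueCalibration]],
                        frag_fraction: float = 0.7,
                        e_threshold: float = 1e-6,
                        species: str = "?") -> CompletenessRow:
    """Classify each conserved single-copy gene as complete, fragmented or
    missing in the assembly.

    A gene is complete when its best significant hit covers at least
    ``frag_fraction`` of the profile's match states, fragmented when a
    significant hit falls short of that coverage, missing without any
    significant hit.
    """
    if not reference_set:
        raise OrthologyError("empty reference profile set")
    if not (0.0 < frag_fraction < 1.0):
        raise OrthologyError("frag_fraction must be in (0, 1)")
    n_complete = n_frag = n_miss = 0
    for profile, cal in reference_set:
        hits = search(profile, cal, assembly, e_threshold=e_threshold)
        if not hits:
            n_miss += 1
            continue
        best_cov = max((h.model_end - h.model_start) / profile.n_match
                       for h in hits)
        if best_cov >= frag_fraction:
            n_complete += 1
        else:
            n_frag += 1
    n = len(reference_set)
    return CompletenessRow(species=species, complete=100.0 * n_complete / n,
                           fragmented=100.0 * n_frag / n,
                           missing=100.0 * n_miss / n)


def summarize_completeness(rows: TypingSequence[CompletenessRow]) -> pd.DataFrame:
    """Min, quartiles (type-7 linear interpolation), median, mean, max of the
    complete/fragmented/missing percentages over species."""
    if not rows:
        raise OrthologyError("no completeness rows")
    df = pd.DataFrame({"complete": [r.complete for r in rows],
                       "fragmented": [r.fragmented for r in rows],
                       "missing": [r.missing for r in rows]})
    stats = pd.DataFrame({
        "min": df.min(),
        "q1": df.quantile(0.25, interpolation="linear"),
        "median": df.median(),
        "mean": df.mean(),
        "q3": df.quantile(0.75, interpolation="linear"),
        "max": df.max(),
    }).T
    return stats


def completeness_to_tsv(rows: TypingSequence[CompletenessRow]) -> str:
    lines = ["species\tcomplete\tfragmented\tmissing"]
    for r in rows:
        lines.append(f"{r.species}\t{r.complete:.1f}\t{r.fragmented:.1f}\t{r.missing:.1f}")
    return "\n".join(lines) + "\n"
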