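"""Sequence and alignment primitives shared by every pipeline stage.

Holds the basic value types (:class:`Sequence`, :class:`Msa`,
:class:`CodonAlignment`, :class:`ScoringScheme`), six-frame translation,
affine-gap local alignment, protein→codon back-translation, and FASTA /
Stockholm / Newick I/O.  Conventions used throughout the package:

* coordinates are 0-based, half-open;
* strand is recorded as a frame label ``+1..+3`` / ``-1..-3``;
* stop codons translate to ``'*'`` and are kept in-frame (downstream
  profile search assigns them zero emission probability, which confines
  matches to stop-free stretches without an explicit ORF caller);
* the standard genetic code is the default, injectable for testing.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence as TypingSequence

import dendropy
from Bio import AlignIO, SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NT = "nucleotide"
AA = "amino-acid"
CODON = "codon"

GAP = "-"

# IUPAC nucleotide one-letter codes (T and U both accepted on input).
IUPAC_NT = set("ACGTUNRYSWKMBDHV")
# Amino acids incl. ambiguity 'X', stop '*', and gap for aligned rows.
AA_LETTERS = set("ACDEFGHIKLMNPQRSTVWYX*")

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]


def standard_genetic_code() -> dict[str, str]:
    """Codon→amino-acid map for the standard code, stops mapped to '*'."""
    code = dict(_STANDARD_TABLE.forward_table)
    for stop in _STANDARD_TABLE.stop_codons:
        code[stop] = "*"
    return code


_COMPLEMENT = str.maketrans("ACGTUNRYSWKMBDHVacgtunryswkmbdhv",
                            "TGCAANYRSWMKVHDBtgcaanyrswmkvhdb")


class SequenceError(ValueError):
    """Malformed sequence, alignment or file content."""


@dataclass
class Sequence:
    """A named sequence over a declared alphabet.

    ``frame`` is only meaningful for translated frames (+1..+3 forward,
    -1..-3 on the reverse complement).
    """

    id: str
    residues: str
    alphabet: str = NT
    frame: int | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("sequence id must be non-empty")
        if self.alphabet == NT:
            bad = set(self.residues.upper()) - IUPAC_NT - {GAP}
            if bad:
                raise SequenceError(
                    f"non-IUPAC nucleotide symbol {sorted(bad)[0]!r} in {self.id!r}")
        elif self.alphabet == AA:
            bad = set(self.residues.upper()) - AA_LETTERS - {GAP}
            if bad:
                raise SequenceError(
                    f"invalid amino-acid symbol {sorted(bad)[0]!r} in {self.id!r}")

    def __len__(self) -> int:
        return len(self.residues)

    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")

    def reverse_complement(self) -> "Sequence":
        if self.alphabet != NT:
            raise SequenceError("reverse complement requires a nucleotide sequence")
        return Sequence(self.id, self.residues.translate(_COMPLEMENT)[::-1], NT)


def reverse_complement(residues: str) -> str:
    """Reverse complement of a raw nucleotide string."""
    return residues.translate(_COMPLEMENT)[::-1]


def translate(nt: str, code: Mapping[str, str] | None = None) -> str:
    """Translate frame +1; stops as '*', ambiguity codons as 'X', partial
    trailing codon dropped."""
    code = code if code is not None else standard_genetic_code()
    seq = nt.upper().replace("U", "T")
    out = []
    for i in range(0, len(seq) - 2, 3):
        out.append(code.get(seq[i:i + 3], "X"))
    return "".join(out)


def translate_six_frames(nt: Sequence,
                         code: Mapping[str, str] | None = None) -> list[Sequence]:
    """All six conceptual translations of a transcript.

    Returns frames in the order +1, +2, +3, -1, -2, -3; frame -k is frame +k
    of the reverse complement.  Raises on empty input or on a sequence too
    short to contain a codon.
    """
    if nt.alphabet != NT:
        raise SequenceError(f"six-frame translation requires nucleotides, got {nt.alphabet}")
    if len(nt) == 0:
        raise SequenceError(f"cannot translate empty sequence {nt.id!r}")
    if len(nt) < 3:
        raise SequenceError(f"sequence {nt.id!r} shorter than one codon")
    frames: list[Sequence] = []
    fwd = nt.residues
    rev = reverse_complement(fwd)
    for strand_seq, sign in ((fwd, +1), (rev, -1)):
        for off in range(3):
            frame = sign * (off + 1)
            frames.append(Sequence(f"{nt.id}|frame{frame:+d}",
                                   translate(strand_seq[off:], code),
                                   AA, frame=frame))
    return frames


@dataclass
class Msa:
    """A multiple sequence alignment; all rows equal length, gap '-'."""

    rows: list[Sequence]

    def __post_init__(self) -> None:
        if not self.rows:
            raise SequenceError("alignment has no rows")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise SequenceError(f"ragged alignment: row lengths {sorted(lengths)}")
        ids = [r.id for r in self.rows]
        if len(set(ids)) != len(ids):
            raise SequenceError("duplicate row ids in alignment")

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def column(self, j: int) -> str:
        return "".join(r.residues[j] for r in self.rows)

    def ids(self) -> list[str]:
        return [r.id for r in self.rows]


@dataclass
class CodonAlignment:
    """Nucleotide alignment whose columns come in in-frame triplets."""

    rows: list[Sequence]

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise SequenceError("ragged codon alignment")
        if self.length % 3 != 0:
            raise SequenceError(f"codon alignment length {self.length} not divisible by 3")

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @property
    def n_codons(self) -> int:
        return self.length // 3

    def codon(self, row: int, j: int) -> str:
        return self.rows[row].residues[3 * j:3 * j + 3]

    def ids(self) -> list[str]:
        return [r.id for r in self.rows]

    def to_protein_msa(self, code: Mapping[str, str] | None = None) -> Msa:
        """Translate each row codon-wise; gap triplets become protein gaps."""
        code = code if code is not None else standard_genetic_code()
        rows = []
        for r in self.rows:
            aas = []
            for j in range(self.n_codons):
                cod = r.residues[3 * j:3 * j + 3]
                aas.append(GAP if cod == GAP * 3 else code.get(cod, "X"))
            rows.append(Sequence(r.id, "".join(aas), AA))
        return Msa(rows)


@dataclass
class ScoringScheme:
    """Amino-acid substitution scores with affine gap costs.

    A gap of length k costs ``-(gap_open + k * gap_extend)`` with both
    stored as negative numbers; defaults mirror BLASTP (BLOSUM62, -11/-1).
    """

    matrix: "substitution_matrices.Array" = field(
        default_factory=lambda: substitution_matrices.load("BLOSUM62"))
    gap_open: float = -11.0
    gap_extend: float = -1.0

    def __post_init__(self) -> None:
        if self.gap_extend < self.gap_open:
            raise SequenceError("gap_extend must be >= gap_open (less penalizing)")

    def pair_score(self, a: str, b: str) -> float:
        alpha = self.matrix.alphabet
        a = a if a in alpha else "X"
        b = b if b in alpha else "X"
        return float(self.matrix[a, b])


def _sanitize_for_matrix(residues: str, alphabet: str) -> str:
    return "".join(c if c in alphabet else "X" for c in residues.upper())


def local_align(a: Sequence, b: Sequence,
                scheme: ScoringScheme | None = None) -> tuple[float, tuple[int, int, int, int]]:
    """Optimal Smith–Waterman–Gotoh local alignment score and region.

    Returns ``(score, (a_start, a_end, b_start, b_end))`` with half-open
    0-based coordinates of the aligned region.  Residues unknown to the
    matrix are scored as 'X'.
    """
    scheme = scheme or ScoringScheme()
    if len(a) == 0 or len(b) == 0:
        raise SequenceError("local alignment requires non-empty sequences")
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = scheme.matrix
    # Bio convention: open_gap_score already includes the first gap column.
    aligner.open_gap_score = scheme.gap_open + scheme.gap_extend
    aligner.extend_gap_score = scheme.gap_extend
    sa = _sanitize_for_matrix(a.residues, scheme.matrix.alphabet)
    sb = _sanitize_for_matrix(b.residues, scheme.matrix.alphabet)
    score = float(aligner.score(sa, sb))
    if score <= 0:
        return 0.0, (0, 0, 0, 0)
    aln = aligner.align(sa, sb)[0]
    blocks_a, blocks_b = aln.aligned
    region = (int(blocks_a[0][0]), int(blocks_a[-1][1]),
              int(blocks_b[0][0]), int(blocks_b[-1][1]))
    return score, region


def percent_identity(a: Sequence, b: Sequence,
                     scheme: ScoringScheme | None = None) -> float:
    """Identity (%) over the local alignment, relative to the shorter sequence."""
    scheme = scheme or ScoringScheme()
    score, _ = local_align(a, b, scheme)
    if score <= 0:
        return 0.0
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = scheme.matrix
    aligner.open_gap_score = scheme.gap_open + scheme.gap_extend
    aligner.extend_gap_score = scheme.gap_extend
    sa = _sanitize_for_matrix(a.residues, scheme.matrix.alphabet)
    sb = _sanitize_for_matrix(b.residues, scheme.matrix.alphabet)
    aln = aligner.align(sa, sb)[0]
    ident = 0
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        ident += sum(1 for x, y in zip(sa[a0:a1], sb[b0:b1]) if x == y)
    return 100.0 * ident / min(len(sa), len(sb))


def backtranslate(protein_msa: Msa, cds: Mapping[str, str | Sequence],
                  code: Mapping[str, str] | None = None) -> CodonAlignment:
    """Thread coding sequences onto a protein alignment blueprint.

    Each protein gap column becomes a ``---`` codon column; in-frame codons
    are preserved verbatim.  Every CDS must translate (frame +1) exactly to
    its ungapped, stop-free protein row.
    """
    code = code if code is not None else standard_genetic_code()
    rows = []
    for ri, prow in enumerate(protein_msa.rows):
        raw = cds.get(prow.id)
        if raw is None:
            raise SequenceError(f"no CDS provided for row {prow.id!r}")
        nt = raw.residues if isinstance(raw, Sequence) else raw
        nt = nt.upper().replace("U", "T")
        protein = prow.ungapped()
        if len(nt) != 3 * len(protein):
            raise SequenceError(
                f"CDS length {len(nt)} != 3 x protein length {len(protein)} for {prow.id!r}")
        aa_from_cds = translate(nt, code)
        for ci, (want, got) in enumerate(zip(protein, aa_from_cds)):
            if want != got:
                raise SequenceError(
                    f"translation mismatch for row {prow.id!r} at protein position "
                    f"{ci}: alignment has {want!r}, CDS gives {got!r}")
        out = []
        k = 0
        for col in prow.residues:
            if col == GAP:
                out.append(GAP * 3)
            else:
                out.append(nt[3 * k:3 * k + 3])
                k += 1
        rows.append(Sequence(prow.id, "".join(out), NT))
    return CodonAlignment(rows)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_fasta(path, alphabet: str = NT) -> list[Sequence]:
    seqs = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SequenceError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seqs.append(Sequence(rec.id, str(rec.seq).upper(), alphabet))
    return seqs


def write_fasta(path, seqs: Iterable[Sequence], wrap: int = 80) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.residues), wrap):
                fh.write(s.residues[i:i + wrap] + "\n")


def read_stockholm(path, alphabet: str = AA) -> Msa:
    aln = AlignIO.read(str(path), "stockholm")
    rows = [Sequence(rec.id, str(rec.seq).upper().replace(".", GAP), alphabet)
            for rec in aln]
    return Msa(rows)


def write_stockholm(path, msa: Msa) -> None:
    records = [SeqRecord(Seq(r.residues), id=r.id, description="") for r in msa.rows]
    aln = AlignIO.MultipleSeqAlignment(records)
    with open(path, "w") as fh:
        AlignIO.write(aln, fh, "stockholm")


def _check_parens(text: str) -> None:
    depth = 0
    for i, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise SequenceError(f"unbalanced ')' at byte offset {i}")
    if depth != 0:
        raise SequenceError(f"unbalanced '(' (depth {depth} at end of input)")


def read_newick(source) -> dendropy.Tree:
    """Read a rooted Newick tree from a path or a literal string."""
    text = source if isinstance(source, str) and ("(" in source or ";" in source) \
        else open(source).read()
    _check_parens(text)
    tree = dendropy.Tree.get(data=text, schema="newick",
                             preserve_underscores=True)
    tree.is_rooted = True
    return tree


def write_newick(tree: dendropy.Tree, path=None) -> str:
    text = tree.as_string(schema="newick", unquoted_underscores=True,
                          suppress_rooting=True).strip()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text


def newick_string(tree: dendropy.Tree) -> str:
    return write_newick(tree)
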