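"""Synthetic data with the statistical structure the pipeline assumes.

Generates random species trees (Yule process), binary gain/loss histories
of gene presence, protein families with fixed domain architectures evolved
along the tree, shared-domain decoy paralogs, fragmented transcriptome
assemblies bracketing a target completeness, and codon alignments evolved
under branch-specific ω with a full per-branch substitution event record.

Every generator is a pure function of (config, seed); ground truth is kept
alongside each dataset so downstream stages can be scored exactly without
re-simulation.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np

from .phmm import AAS
from .phylo import edge_key, find_stem_edge, label_internal_nodes
from .seqcore import (AA, NT, CodonAlignment, Msa, Sequence, SequenceError,
                      standard_genetic_code, write_fasta, write_newick,
                      write_stockholm)
from .selection import CODONS, CODON_AA, CODON_INDEX, N_CODONS, codon_rate_matrix

_N_AA = len(AAS)

# sense codons per amino acid, for uniform synonymous back-translation
_SYN: dict[str, list[str]] = {}
for _c, _a in zip(CODONS, CODON_AA):
    _SYN.setdefault(_a, []).append(_c)


class SynthError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Species trees
# ---------------------------------------------------------------------------

def gen_species_tree(n_leaves: int, seed: int, birth_rate: float = 1.0) -> dendropy.Tree:
    """Random rooted binary tree from a Yule (pure-birth) process.

    Exponential waiting times with rate ``birth_rate × lineages``; leaf
    labels sp01..spNN in creation order; internal nodes labelled n0.. in
    postorder at the end.  Deterministic per seed.
    """
    if n_leaves < 4:
        raise SynthError("need at least 4 leaves")
    rng = np.random.default_rng(seed)
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.is_rooted = True
    root = tree.seed_node
    c1, c2 = dendropy.Node(), dendropy.Node()
    root.add_child(c1)
    root.add_child(c2)
    start = {id(c1): 0.0, id(c2): 0.0}
    active = [c1, c2]
    t = 0.0
    while len(active) < n_leaves:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        idx = int(rng.integers(len(active)))
        nd = active.pop(idx)
        nd.edge.length = t - start.pop(id(nd))
        a, b = dendropy.Node(), dendropy.Node()
        nd.add_child(a)
        nd.add_child(b)
        start[id(a)] = start[id(b)] = t
        active.extend([a, b])
    t += rng.exponential(1.0 / (birth_rate * len(active)))
    width = len(str(n_leaves))
    for i, nd in enumerate(active):
        nd.edge.length = t - start.pop(id(nd))
        nd.taxon = tns.new_taxon(f"sp{i + 1:0{width}d}")
    label_internal_nodes(tree)
    return tree


# ---------------------------------------------------------------------------
# Presence/absence histories
# ---------------------------------------------------------------------------

@dataclass
class PresenceTruth:
    characters: list[dict[str, int]]          # per character: species -> 0/1
    events: list[list[tuple[str, str]]]       # per character: (edge key, gain|loss)
    root_states: list[int]
    status: str = "ok"


def simulate_presence(tree: dendropy.Tree, gain_rate: float, loss_rate: float,
                      n_characters: int, seed: int,
                      force_root_gain: bool = False) -> PresenceTruth:
    """Two-state Markov gain/loss process down the tree from an absent root.

    Per-branch transition probabilities follow the 2-state CTMC with the
    given rates; recorded events are net state changes per branch.
    """
    if gain_rate < 0 or loss_rate < 0:
        raise SynthError("rates must be non-negative")
    label_internal_nodes(tree)
    rng = np.random.default_rng(seed)
    root_state = 1 if force_root_gain else 0
    status = "ok"
    if gain_rate == 0 and loss_rate == 0 and root_state == 0:
        status = "all-absent"
    chars, events_all, roots = [], [], []
    tot = gain_rate + loss_rate
    for _ in range(n_characters):
        states = {id(tree.seed_node): root_state}
        events: list[tuple[str, str]] = []
        for nd in tree.preorder_node_iter():
            if nd is tree.seed_node:
                continue
            t = float(nd.edge.length or 0.0)
            parent = states[id(nd.parent_node)]
            if tot == 0:
                child = parent
            else:
                eq1 = gain_rate / tot
                decay = math.exp(-tot * t)
                p1 = eq1 + (parent - eq1) * decay  # P(state 1 | parent)
                child = 1 if rng.random() < p1 else 0
            states[id(nd)] = child
            if child != parent:
                events.append((edge_key(nd), "gain" if child else "loss"))
        chars.append({lf.taxon.label: states[id(lf)]
                      for lf in tree.leaf_node_iter()})
        events_all.append(events)
        roots.append(root_state)
    return PresenceTruth(characters=chars, events=events_all,
                         root_states=roots, status=status)


# ---------------------------------------------------------------------------
# Protein families with domain architectures
# ---------------------------------------------------------------------------

_DOMAIN_LENGTHS = {"zf-C2H2": 23, "zf-BED": 50, "zf-AD": 30, "BTB": 40,
                   "GAGA": 25, "FLYWCH": 30, "BESS": 40, "BEN": 35}


def domain_motif(name: str, length: int | None = None) -> str:
    """Deterministic amino-acid motif for a named domain (shared library)."""
    length = length or _DOMAIN_LENGTHS.get(name, 25)
    rng = np.random.default_rng(zlib.crc32(name.encode()) & 0x7FFFFFFF)
    return "".join(AAS[i] for i in rng.integers(_N_AA, size=length))


@dataclass
class FamilyConfig:
    name: str
    architecture: list[tuple[str, int]]       # (domain, copy count), ordered
    linker_length: int = 12
    divergence: float = 0.08                  # substitutions/site per unit branch

    def __post_init__(self) -> None:
        if not self.architecture:
            raise SynthError("empty domain architecture")
        if any(c < 1 for _, c in self.architecture):
            raise SynthError("domain copy counts must be >= 1")
        if self.divergence < 0:
            raise SynthError("divergence must be >= 0")


@dataclass
class FamilyResult:
    config: FamilyConfig
    ancestral: str
    per_species: dict[str, str]
    seed_msa: Msa
    domain_truth: list[tuple[str, int, int]]  # (domain, start, end) half-open


def _mutate(protein: str, p: float, rng: np.random.Generator) -> str:
    out = list(protein)
    for i in range(len(out)):
        if rng.random() < p:
            choices = [a for a in AAS if a != out[i]]
            out[i] = choices[int(rng.integers(len(choices)))]
    return "".join(out)


def gen_family(config: FamilyConfig, tree: dendropy.Tree, seed: int,
               n_seed_rows: int = 5, seed_divergence: float = 0.06) -> FamilyResult:
    """Evolve a domain-architecture protein family along the species tree.

    The ancestral protein concatenates the shared domain motifs (in
    architecture order, with fixed-length random linkers); evolution is
    i.i.d. per-site substitution at the configured divergence, with no
    indels, so domain coordinates are identical in every species.  The
    seed alignment rows are independent mutants of the ancestor, standing
    in for previously published family members.
    """
    rng = np.random.default_rng(seed)
    parts, truth = [], []
    pos = 0
    for dom, count in config.architecture:
        motif = domain_motif(dom)
        for _ in range(count):
            if parts:
                linker = "".join(AAS[i] for i in rng.integers(_N_AA, size=config.linker_length))
                parts.append(linker)
                pos += config.linker_length
            truth.append((dom, pos, pos + len(motif)))
            parts.append(motif)
            pos += len(motif)
    ancestral = "".join(parts)

    label_internal_nodes(tree)
    seqs = {id(tree.seed_node): ancestral}
    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node:
            continue
        t = float(nd.edge.length or 0.0)
        p = 1.0 - math.exp(-config.divergence * t)
        seqs[id(nd)] = _mutate(seqs[id(nd.parent_node)], p, rng)
    per_species = {lf.taxon.label: seqs[id(lf)] for lf in tree.leaf_node_iter()}

    rows = [Sequence(f"{config.name}_ref{i + 1}",
                     _mutate(ancestral, seed_divergence, rng), AA)
            for i in range(n_seed_rows)]
    return FamilyResult(config=config, ancestral=ancestral,
                        per_species=per_species, seed_msa=Msa(rows),
                        domain_truth=truth)


def gen_domain_seed_msa(domain: str, n_rows: int = 5, divergence: float = 0.06,
                        seed: int = 0) -> Msa:
    """Seed alignment for a single domain profile: independent mutants of
    the shared domain motif."""
    rng = np.random.default_rng(seed)
    motif = domain_motif(domain)
    rows = [Sequence(f"{domain}_r{i + 1}", _mutate(motif, divergence, rng), AA)
            for i in range(n_rows)]
    return Msa(rows)


def gen_decoy_proteins(shared_domains: list[str], n: int, seed: int,
                       min_backbone: int = 120, max_backbone: int = 240) -> list[Sequence]:
    """Non-orthologous proteins that nevertheless carry the shared domain
    motifs (the Su(Kpn)/FLYWCH-style confounder)."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        dom = shared_domains[int(rng.integers(len(shared_domains)))]
        motif = domain_motif(dom)
        motif = _mutate(motif, 0.08, rng)
        blen = int(rng.integers(min_backbone, max_backbone))
        backbone = "".join(AAS[j] for j in rng.integers(_N_AA, size=blen))
        ins = int(rng.integers(blen - 1))
        copies = 1 + int(rng.random() < 0.3)
        body = backbone[:ins] + (motif * copies) + backbone[ins:]
        out.append(Sequence(f"decoy{i + 1}", body, AA))
    return out


# ---------------------------------------------------------------------------
# Transcriptome assembly simulation
# ---------------------------------------------------------------------------

def backtranslate_protein(protein: str, rng: np.random.Generator) -> str:
    """Uniform synonymous codon choice; input must be stop-free."""
    out = []
    for aa in protein:
        opts = _SYN.get(aa)
        if not opts:
            raise SynthError(f"cannot back-translate residue {aa!r}")
        out.append(opts[int(rng.integers(len(opts)))])
    return "".join(out)


@dataclass
class FragParams:
    fragment_prob: float = 0.5     # among non-complete genes: fragment vs drop
    min_frac: float = 0.25
    max_frac: float = 0.60


def _random_nt(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(4, size=length))


def gen_transcriptome(proteome: dict[str, str], completeness_target: float,
                      frag_params: FragParams | None = None, n_noise: int = 0,
                      seed: int = 0,
                      utr_range: tuple[int, int] = (20, 80),
                      noise_length: tuple[int, int] = (200, 600)
                      ) -> tuple[list[Sequence], dict[str, str], dict[str, str]]:
    """Simulate an assembled transcriptome from a proteome.

    Each protein is back-translated with uniform synonymous codon usage,
    kept full-length with probability ``completeness_target`` (else
    fragmented or dropped), embedded in random UTR-like flanks on a random
    strand.  Returns the transcripts, the per-gene truth
    ('complete' | 'fragmented' | 'missing'), and the strand ('+' | '-')
    each planted CDS ended up on.
    """
    if not proteome:
        raise SynthError("empty proteome")
    if not (0.0 < completeness_target <= 1.0):
        raise SynthError("completeness_target must be in (0, 1]")
    fp = frag_params or FragParams()
    rng = np.random.default_rng(seed)
    transcripts: list[Sequence] = []
    truth: dict[str, str] = {}
    strands: dict[str, str] = {}
    for gene in sorted(proteome):
        protein = proteome[gene]
        u = rng.random()
        if u < completeness_target:
            kept, status = protein, "complete"
        elif rng.random() < fp.fragment_prob:
            frac = fp.min_frac + (fp.max_frac - fp.min_frac) * rng.random()
            n_keep = max(5, int(round(frac * len(protein))))
            start = int(rng.integers(0, len(protein) - n_keep + 1))
            kept, status = protein[start:start + n_keep], "fragmented"
        else:
            kept, status = None, "missing"
        truth[gene] = status
        if kept is None:
            continue
        cds = backtranslate_protein(kept, rng)
        utr5 = _random_nt(rng, int(rng.integers(*utr_range)))
        utr3 = _random_nt(rng, int(rng.integers(*utr_range)))
        nt = utr5 + cds + utr3
        if rng.random() < 0.5:
            nt = Sequence("tmp", nt).reverse_complement().residues
            strands[gene] = "-"
        else:
            strands[gene] = "+"
        transcripts.append(Sequence(f"tr_{gene}", nt, NT))
    for i in range(n_noise):
        transcripts.append(Sequence(
            f"noise{i + 1}", _random_nt(rng, int(rng.integers(*noise_length))), NT))
    return transcripts, truth, strands


# ---------------------------------------------------------------------------
# Codon alignment simulation (Gillespie, event-recording)
# ---------------------------------------------------------------------------

@dataclass
class CodonSimTruth:
    kappa: float
    omega_by_class: dict[str, float]
    branch_classes: dict[str, str]
    events: dict[str, list[tuple[int, int, int]]]  # edge -> (site, from, to)
    n_syn: dict[str, int]
    n_nonsyn: dict[str, int]


def simulate_codon_alignment(tree: dendropy.Tree, kappa: float,
                             omega_by_class: dict[str, float],
                             pi: np.ndarray | None, n_codons: int, seed: int,
                             foreground=None) -> tuple[CodonAlignment, CodonSimTruth]:
    """Evolve codon sequences down the tree under a branch-class ω model.

    Root codons are drawn from π; each branch evolves per site by Gillespie
    simulation of the (scaled) generator, so branch lengths are expected
    substitutions per codon site and every substitution event is recorded.
    Stops are never emitted (the state space is the 61 sense codons).
    """
    if n_codons < 1:
        raise SynthError("n_codons must be >= 1")
    for cls, om in omega_by_class.items():
        if om < 0:
            raise SynthError(f"omega for class {cls!r} must be >= 0")
    pi = np.full(N_CODONS, 1.0 / N_CODONS) if pi is None else np.asarray(pi)
    label_internal_nodes(tree)
    classes: dict[str, str] = {}
    if foreground is not None:
        fg_node = find_stem_edge(tree, foreground)
        classes[edge_key(fg_node)] = "foreground"
    Qs = {cls: codon_rate_matrix(kappa, om, pi) for cls, om in omega_by_class.items()}
    rng = np.random.default_rng(seed)
    root_seq = rng.choice(N_CODONS, size=n_codons, p=pi)
    states = {id(tree.seed_node): root_seq}
    events: dict[str, list[tuple[int, int, int]]] = {}
    n_syn: dict[str, int] = {}
    n_nonsyn: dict[str, int] = {}
    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node:
            continue
        key = edge_key(nd)
        t_total = float(nd.edge.length or 0.0)
        cls = classes.get(key, "background")
        Q = Qs[cls]
        parent = states[id(nd.parent_node)]
        child = parent.copy()
        ev: list[tuple[int, int, int]] = []
        for s in range(n_codons):
            c = int(child[s])
            t = 0.0
            while True:
                rate = -Q[c, c]
                if rate <= 0:
                    break
                t += rng.exponential(1.0 / rate)
                if t >= t_total:
                    break
                probs = Q[c].copy()
                probs[c] = 0.0
                probs /= probs.sum()
                nxt = int(rng.choice(N_CODONS, p=probs))
                ev.append((s, c, nxt))
                c = nxt
            child[s] = c
        states[id(nd)] = child
        events[key] = ev
        n_syn[key] = sum(1 for _, a, b in ev if CODON_AA[a] == CODON_AA[b])
        n_nonsyn[key] = len(ev) - n_syn[key]
    rows = [Sequence(lf.taxon.label,
                     "".join(CODONS[int(c)] for c in states[id(lf)]), NT)
            for lf in tree.leaf_node_iter()]
    truth = CodonSimTruth(kappa=kappa, omega_by_class=dict(omega_by_class),
                          branch_classes=classes, events=events,
                          n_syn=n_syn, n_nonsyn=n_nonsyn)
    return CodonAlignment(rows), truth


# ---------------------------------------------------------------------------
# Default synthetic panel
# ---------------------------------------------------------------------------

DEFAULT_FAMILIES = [
    FamilyConfig("CTCF-like", [("zf-C2H2", 11)]),
    FamilyConfig("SuHw-like", [("zf-C2H2", 12)]),
    FamilyConfig("CP190-like", [("BTB", 1), ("zf-C2H2", 4)]),
    FamilyConfig("GAF-like", [("BTB", 1), ("GAGA", 1)]),
    FamilyConfig("Modmdg4-like", [("BTB", 1), ("FLYWCH", 1)]),
    FamilyConfig("Pita-like", [("zf-AD", 1), ("zf-C2H2", 10)]),
]


@dataclass
class PanelConfig:
    n_species: int = 12
    families: list[FamilyConfig] = field(default_factory=lambda: list(DEFAULT_FAMILIES))
    n_conserved: int = 20
    conserved_length: int = 90
    completeness_range: tuple[float, float] = (0.15, 0.81)
    n_noise: int = 8
    n_decoys_per_species: int = 2
    gain_rate: float = 0.25
    loss_rate: float = 0.15
    birth_rate: float = 1.0
    n_references: int = 2


@dataclass
class Panel:
    config: PanelConfig
    seed: int
    tree: dendropy.Tree
    species: list[str]
    presence: dict[str, dict[str, int]]       # gene -> species -> 0/1
    presence_events: dict[str, list[tuple[str, str]]]
    families: dict[str, FamilyResult]
    references: list                          # orthology.ReferenceProteome
    assemblies: dict[str, list[Sequence]]
    conserved_seed_msas: dict[str, Msa]
    conserved_truth: dict[str, dict[str, str]]
    completeness_targets: dict[str, float]
    domain_seed_msas: dict[str, Msa] = field(default_factory=dict)
    decoy_pool: list[Sequence] = field(default_factory=list)
    codon_alignments: dict[str, CodonAlignment] = field(default_factory=dict)
    selection_specs: dict[str, dict] = field(default_factory=dict)

    def gene_names(self) -> list[str]:
        return [f.config.name for f in self.families.values()]

    def truth_matrix(self):
        import pandas as pd
        return pd.DataFrame(self.presence)[self.gene_names()].loc[self.species]


def generate_panel(config: PanelConfig | None = None, seed: int = 1) -> Panel:
    """Build the default synthetic study panel: a species tree, gain/loss
    histories per gene family, per-species transcriptome assemblies with
    planted orthologs, decoy paralogs, conserved single-copy genes for
    completeness assessment, and pooled reference proteomes."""
    from .orthology import ReferenceProteome

    cfg = config or PanelConfig()
    rng = np.random.default_rng(seed)
    tree = gen_species_tree(cfg.n_species, seed=seed, birth_rate=cfg.birth_rate)
    species = [lf.taxon.label for lf in tree.leaf_node_iter()]

    presence: dict[str, dict[str, int]] = {}
    presence_events: dict[str, list[tuple[str, str]]] = {}
    families: dict[str, FamilyResult] = {}
    for i, fam_cfg in enumerate(cfg.families):
        truth = simulate_presence(tree, cfg.gain_rate, cfg.loss_rate, 1,
                                  seed=int(rng.integers(2**31)),
                                  force_root_gain=(i % 2 == 0))
        presence[fam_cfg.name] = truth.characters[0]
        presence_events[fam_cfg.name] = truth.events[0]
        families[fam_cfg.name] = gen_family(fam_cfg, tree,
                                            seed=int(rng.integers(2**31)))

    shared = sorted({d for f in cfg.families for d, _ in f.architecture})
    decoy_pool = gen_decoy_proteins(shared, max(3 * cfg.n_decoys_per_species, 6),
                                    seed=int(rng.integers(2**31)))
    domain_seed_msas = {d: gen_domain_seed_msa(d, seed=int(rng.integers(2**31)))
                        for d in shared}

    references = []
    for r in range(cfg.n_references):
        entries = []
        for fam in families.values():
            variant = _mutate(fam.ancestral, 0.05, rng)
            entries.append((Sequence(f"ref{r + 1}_{fam.config.name}", variant, AA),
                            fam.config.name))
        # every decoy family is represented in the references, mirroring a
        # comprehensive nr-style database: a decoy candidate's reciprocal
        # best hit is then its own family, not the claimed gene
        for d in decoy_pool:
            entries.append((Sequence(f"ref{r + 1}_{d.id}",
                                     _mutate(d.residues, 0.05, rng), AA), "other"))
        references.append(ReferenceProteome(species=f"refsp{r + 1}", entries=entries))

    conserved_seed_msas: dict[str, Msa] = {}
    conserved_base: dict[str, str] = {}
    for g in range(cfg.n_conserved):
        name = f"cons{g + 1:03d}"
        base = "".join(AAS[j] for j in rng.integers(_N_AA, size=cfg.conserved_length))
        conserved_base[name] = base
        rows = [Sequence(f"{name}_r{i + 1}", _mutate(base, 0.05, rng), AA)
                for i in range(4)]
        conserved_seed_msas[name] = Msa(rows)

    assemblies: dict[str, list[Sequence]] = {}
    conserved_truth: dict[str, dict[str, str]] = {}
    completeness_targets: dict[str, float] = {}
    lo, hi = cfg.completeness_range
    for sp in species:
        target = lo + (hi - lo) * rng.random()
        completeness_targets[sp] = target
        ibp_proteome = {fam.config.name: fam.per_species[sp]
                        for fam in families.values()
                        if presence[fam.config.name][sp] == 1}
        sub_seed = int(rng.integers(2**31))
        transcripts: list[Sequence] = []
        if ibp_proteome:
            ibp_tr, _, _ = gen_transcriptome(ibp_proteome, 1.0, seed=sub_seed)
            transcripts.extend(ibp_tr)
        cons_proteome = {name: _mutate(base, 0.03, rng)
                         for name, base in conserved_base.items()}
        cons_tr, cons_t, _ = gen_transcriptome(cons_proteome, target,
                                            n_noise=cfg.n_noise,
                                            seed=int(rng.integers(2**31)))
        transcripts.extend(cons_tr)
        conserved_truth[sp] = cons_t
        dstart = int(rng.integers(len(decoy_pool)))
        for k in range(cfg.n_decoys_per_species):
            d = decoy_pool[(dstart + k) % len(decoy_pool)]
            nt = backtranslate_protein(d.residues, rng)
            transcripts.append(Sequence(f"tr_decoy_{sp}_{k}", nt, NT))
        assemblies[sp] = transcripts

    # per-gene codon alignments on the tree pruned to the species carrying
    # the gene, with a designated foreground branch; the first eligible
    # gene evolves under positive selection (omega_fg = 4), the rest
    # neutrally -- inputs for the selection and gene-tree stages
    codon_alignments: dict[str, CodonAlignment] = {}
    selection_specs: dict[str, dict] = {}
    positive_assigned = False
    for gene in presence:
        carriers = [sp for sp in species if presence[gene][sp] == 1]
        if len(carriers) < 4:
            continue
        sub = tree.clone(depth=1)
        sub.retain_taxa([lf.taxon for lf in sub.leaf_node_iter()
                         if lf.taxon.label in carriers])
        sub.is_rooted = True
        label_internal_nodes(sub)
        fg_leaf = sorted(carriers)[0]
        omega_fg = 1.0 if positive_assigned else 4.0
        positive_assigned = True
        aln, _ = simulate_codon_alignment(
            sub, kappa=2.0, omega_by_class={"background": 1.0,
                                            "foreground": omega_fg},
            pi=None, n_codons=300, seed=int(rng.integers(2**31)),
            foreground=fg_leaf)
        codon_alignments[gene] = aln
        selection_specs[gene] = {"branch_label": f"{fg_leaf}-stem",
                                 "foreground": fg_leaf,
                                 "true_omega_fg": omega_fg}

    return Panel(config=cfg, seed=seed, tree=tree, species=species,
                 presence=presence, presence_events=presence_events,
                 families=families, references=references,
                 assemblies=assemblies, conserved_seed_msas=conserved_seed_msas,
                 conserved_truth=conserved_truth,
                 completeness_targets=completeness_targets,
                 domain_seed_msas=domain_seed_msas, decoy_pool=decoy_pool,
                 codon_alignments=codon_alignments,
                 selection_specs=selection_specs)


def write_dataset(panel: Panel, outdir) -> None:
    """Serialize a panel as a plain-text dataset directory with its truth."""
    out = Path(outdir)
    (out / "assemblies").mkdir(parents=True, exist_ok=True)
    (out / "references").mkdir(exist_ok=True)
    (out / "seeds").mkdir(exist_ok=True)
    for sp, transcripts in panel.assemblies.items():
        write_fasta(out / "assemblies" / f"{sp}.fasta", transcripts)
    for ref in panel.references:
        write_fasta(out / "references" / f"{ref.species}.fasta",
                    [Sequence(f"{s.id}|gene={g}", s.residues, AA)
                     for s, g in ref.entries])
    for name, fam in panel.families.items():
        write_stockholm(out / "seeds" / f"{name}.stockholm", fam.seed_msa)
    for name, msa in panel.conserved_seed_msas.items():
        write_stockholm(out / "seeds" / f"{name}.stockholm", msa)
    for name, msa in panel.domain_seed_msas.items():
        write_stockholm(out / "seeds" / f"domain_{name}.stockholm", msa)
    write_newick(panel.tree, out / "tree.nwk")
    if panel.codon_alignments:
        (out / "selection").mkdir(exist_ok=True)
        for gene, aln in panel.codon_alignments.items():
            write_fasta(out / "selection" / f"{gene}.fasta", aln.rows)
    truth = {
        "seed": panel.seed,
        "species": panel.species,
        "presence": panel.presence,
        "presence_events": {g: list(map(list, ev))
                            for g, ev in panel.presence_events.items()},
        "domain_truth": {g: list(map(list, fam.domain_truth))
                         for g, fam in panel.families.items()},
        "conserved_truth": panel.conserved_truth,
        "completeness_targets": panel.completeness_targets,
        "selection_specs": panel.selection_specs,
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1))
    cfg = asdict(panel.config)
    cfg["families"] = [asdict(f) for f in panel.config.families]
    (out / "config.json").write_text(json.dumps(cfg, indent=1))
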