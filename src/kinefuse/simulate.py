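"""Fully synthetic cohort generator with planted ground truth.

Generates a miniature annotation (GTF + genome FASTA + kinase registry),
per-sample chimeric-evidence files, a normals panel, and an FPKM-like
expression matrix, with fusions planted as drivers, passengers (out-of-frame
or domain-truncating) and artifacts (normals-panel recurrences,
trans-splicing chimeras, homologous decoys), so that every pipeline stage is
testable without external data.

Gene architecture: exon 1 carries the entire 5'UTR, the CDS starts at the
first base of exon 2, internal exons are pure coding with lengths that are
multiples of three, and the last exon holds the final coding stretch (ending
in a stop codon) plus the 3'UTR.  Junctions placed on exon boundaries are
therefore in frame by construction, and frame intent is enforced by shifting
the donor off the boundary (out-of-frame, cryptic) or by choosing a deeper
acceptor exon (domain truncation).
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from Bio.Seq import Seq

from .annotation import GeneIndex, GeneModel, Transcript
from .evidence import ChimericEvidence, Locus, write_evidence

STOP_CODONS = {"TAA", "TAG", "TGA"}
ROLES = ("driver", "passenger", "normals_artifact", "trans_splice", "homolog_decoy")
FRAME_INTENTS = ("in_frame", "out_of_frame", "promoter")

UTR5_LEN = 120
UTR3_LEN = 150


@dataclass(frozen=True)
class PlantedFusion:
    """One fusion planted into the cohort with known support and frame."""

    gene5: str
    gene3: str
    n_chimeric: int
    n_split: int
    frame_intent: str
    prevalence: float
    role: str = "driver"
    acceptor_exon: int = 2  # transcription-order exon of the 3' gene (1-based)

    def __post_init__(self) -> None:
        if self.n_chimeric < 0 or self.n_split < 0:
            raise ValueError("planted support counts must be >= 0")
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError("prevalence must lie in [0, 1]")
        if self.frame_intent not in FRAME_INTENTS:
            raise ValueError(f"unknown frame intent {self.frame_intent!r}")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")


@dataclass(frozen=True)
class ArtifactSpec:
    """Parameters of the planted confounders."""

    n_normals_carrying: int = 5
    trans_splice_fold: float = 1000.0
    homolog_pairs: tuple[tuple[str, str], ...] = ()
    homolog_mutation_rate: float = 0.01


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_samples: int = 20
    n_normals: int = 10
    n_genes: int = 34
    cohort: str = "COH1"
    kinase_genes: tuple[str, ...] = ()
    planted_fusions: tuple[PlantedFusion, ...] = ()
    artifact_spec: ArtifactSpec = field(default_factory=ArtifactSpec)
    noise: float = 0.002  # Poisson mean of background pair records per gene pair

    def gene_names(self) -> list[str]:
        return [f"GENE{i:03d}" for i in range(1, self.n_genes + 1)]

    def validate(self) -> "SimConfig":
        if self.n_genes < 2:
            raise ValueError("need at least 2 genes")
        names = set(self.gene_names())
        referenced = {g for pf in self.planted_fusions for g in (pf.gene5, pf.gene3)}
        referenced |= set(self.kinase_genes)
        referenced |= {g for pair in self.artifact_spec.homolog_pairs for g in pair}
        missing = sorted(referenced - names)
        if missing:
            raise ValueError(f"planted genes absent from the gene set: {missing}")
        return self


def default_scenario(seed: int = 0, n_samples: int = 20,
                     n_normals: int = 10) -> SimConfig:
    """The reference study design: a 20-sample cohort with six planted
    drivers, four passengers (two out-of-frame, two domain-truncating), two
    normals-panel artifacts, one trans-splicing artifact and one homologous
    decoy pair, plus low-rate background chimeras."""
    planted = (
        PlantedFusion("GENE001", "GENE002", 8, 3, "in_frame", 0.15),
        PlantedFusion("GENE003", "GENE004", 5, 2, "in_frame", 0.10),
        PlantedFusion("GENE005", "GENE006", 10, 1, "in_frame", 0.10),
        PlantedFusion("GENE007", "GENE008", 9, 2, "in_frame", 0.20),
        PlantedFusion("GENE009", "GENE010", 12, 2, "promoter", 0.15),
        PlantedFusion("GENE011", "GENE012", 7, 3, "promoter", 0.10),
        PlantedFusion("GENE013", "GENE014", 8, 3, "out_of_frame", 0.10,
                      role="passenger"),
        PlantedFusion("GENE015", "GENE016", 8, 2, "out_of_frame", 0.10,
                      role="passenger"),
        PlantedFusion("GENE017", "GENE018", 8, 3, "in_frame", 0.10,
                      role="passenger", acceptor_exon=3),
        PlantedFusion("GENE019", "GENE020", 8, 2, "in_frame", 0.10,
                      role="passenger", acceptor_exon=3),
        PlantedFusion("GENE021", "GENE022", 8, 3, "in_frame", 0.10,
                      role="normals_artifact"),
        PlantedFusion("GENE023", "GENE024", 8, 2, "in_frame", 0.15,
                      role="normals_artifact"),
        PlantedFusion("GENE025", "GENE026", 22, 0, "in_frame", 0.10,
                      role="trans_splice"),
        PlantedFusion("GENE027", "GENE028", 8, 3, "in_frame", 0.10,
                      role="homolog_decoy"),
    )
    kinases = tuple(f"GENE{i:03d}" for i in
                    (2, 4, 6, 8, 10, 12, 14, 16, 18, 20, 22, 24, 26, 28))
    return SimConfig(seed=seed, n_samples=n_samples, n_normals=n_normals,
                     n_genes=34, kinase_genes=kinases, planted_fusions=planted,
                     artifact_spec=ArtifactSpec(
                         homolog_pairs=(("GENE027", "GENE028"),))).validate()


# ---------------------------------------------------------------------------
# gene and genome construction
# ---------------------------------------------------------------------------

def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def _rand_cds(rng: np.random.Generator, n_codons: int) -> str:
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = _rand_seq(rng, 3)
        if c not in STOP_CODONS and c != "ATG":
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


@dataclass
class SimGene:
    symbol: str
    gene_id: str
    chrom: str
    strand: str
    exon_t_lens: tuple[int, ...]
    u5: int
    cds_len: int
    u3: int
    t_seq: str
    exons: tuple[tuple[int, int], ...] = ()  # genomic, transcription order
    start: int = 0
    end: int = 0

    @property
    def cds_tspan(self) -> tuple[int, int]:
        return self.u5, self.u5 + self.cds_len

    def transcript(self) -> Transcript:
        cds = sorted(_t_slice_to_genomic(self.exons, self.strand, *self.cds_tspan),
                     reverse=self.strand == "-")
        return Transcript(tx_id=f"{self.gene_id}.t1", strand=self.strand,
                          exons=self.exons, cds=tuple(cds))

    def gene_model(self) -> GeneModel:
        return GeneModel(gene_id=self.gene_id, symbol=self.symbol,
                         chrom=self.chrom, strand=self.strand,
                         start=self.start, end=self.end,
                         transcripts=(self.transcript(),))

    def tpos_to_genomic(self, tpos: int) -> int:
        off = 0
        for s, e in self.exons:
            n = e - s
            if tpos < off + n:
                d = tpos - off
                return s + d if self.strand == "+" else e - 1 - d
            off += n
        raise IndexError(tpos)

    def exon_t_start(self, exon_index: int) -> int:
        """Transcript coordinate of the first base of a 1-based exon index."""
        return sum(self.exon_t_lens[:exon_index - 1])


def _t_slice_to_genomic(exons, strand, t0, t1):
    """Map a transcript-coordinate interval to genomic intervals."""
    out = []
    off = 0
    for s, e in exons:
        n = e - s
        a, b = max(t0, off), min(t1, off + n)
        if a < b:
            if strand == "+":
                out.append((s + (a - off), s + (b - off)))
            else:
                out.append((e - (b - off), e - (a - off)))
        off += n
    return sorted(out)


class _ChromBuilder:
    def __init__(self, name: str):
        self.name = name
        self.parts: list[str] = []
        self.pos = 0

    def append(self, seq: str) -> None:
        self.parts.append(seq)
        self.pos += len(seq)

    def sequence(self) -> str:
        return "".join(self.parts)


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in hits:
        alternatives = [b for b in "ACGT" if b != out[i]]
        out[i] = alternatives[int(rng.integers(0, 3))]
    return "".join(out)


def _make_gene(rng: np.random.Generator, symbol: str, n_exons: int,
               template: Optional[SimGene] = None,
               mutation_rate: float = 0.01) -> SimGene:
    gene_id = "SYNG" + symbol[4:]
    if template is not None:
        return SimGene(symbol=symbol, gene_id=gene_id, chrom="", strand="",
                       exon_t_lens=template.exon_t_lens, u5=template.u5,
                       cds_len=template.cds_len, u3=template.u3,
                       t_seq=_mutate(rng, template.t_seq, mutation_rate))
    codon_counts = [int(rng.integers(40, 90)) for _ in range(n_exons - 1)]
    cds = _rand_cds(rng, sum(codon_counts))
    exon_t_lens = [UTR5_LEN] + [3 * c for c in codon_counts]
    exon_t_lens[-1] += UTR3_LEN
    t_seq = _rand_seq(rng, UTR5_LEN) + cds + _rand_seq(rng, UTR3_LEN)
    return SimGene(symbol=symbol, gene_id=gene_id, chrom="", strand="",
                   exon_t_lens=tuple(exon_t_lens), u5=UTR5_LEN,
                   cds_len=len(cds), u3=UTR3_LEN, t_seq=t_seq)


def _place_gene(rng: np.random.Generator, builder: _ChromBuilder,
                sg: SimGene, strand: str) -> None:
    sg.chrom, sg.strand = builder.name, strand
    builder.append(_rand_seq(rng, int(rng.integers(2000, 5001))))
    pieces = []
    off = 0
    for n in sg.exon_t_lens:
        pieces.append(sg.t_seq[off:off + n])
        off += n
    introns = [int(rng.integers(200, 801)) for _ in range(len(pieces) - 1)]
    order = range(len(pieces)) if strand == "+" else range(len(pieces) - 1, -1, -1)
    placed: dict[int, tuple[int, int]] = {}
    for rank, j in enumerate(order):
        piece = pieces[j] if strand == "+" else str(Seq(pieces[j]).reverse_complement())
        placed[j] = (builder.pos, builder.pos + len(piece))
        builder.append(piece)
        if rank < len(pieces) - 1:
            intron_len = introns[j] if strand == "+" else introns[j - 1]
            builder.append(_rand_seq(rng, intron_len))
    sg.exons = tuple(placed[j] for j in range(len(pieces)))
    sg.start = min(s for s, _ in sg.exons)
    sg.end = max(e for _, e in sg.exons)


@dataclass
class SimulatedAnnotation:
    config: SimConfig
    genes: dict[str, SimGene]
    genome: dict[str, str]

    def index(self) -> GeneIndex:
        return GeneIndex(g.gene_model() for g in self.genes.values())

    # -- writers -----------------------------------------------------------
    def write_gtf(self, path: Path) -> None:
        lines = []
        for sg in sorted(self.genes.values(), key=lambda g: (g.chrom, g.start)):
            tx = sg.transcript()
            attrs = (f'gene_id "{sg.gene_id}"; transcript_id "{sg.gene_id}.t1"; '
                     f'gene_name "{sg.symbol}";')
            gene_attrs = f'gene_id "{sg.gene_id}"; gene_name "{sg.symbol}";'

            def row(feature, s, e, attr):
                return (f"{sg.chrom}\tkinefuse_sim\t{feature}\t{s + 1}\t{e}\t."
                        f"\t{sg.strand}\t.\t{attr}")

            lines.append(row("gene", sg.start, sg.end, gene_attrs))
            lines.append(row("transcript", sg.start, sg.end, attrs))
            for s, e in sorted(tx.exons):
                lines.append(row("exon", s, e, attrs))
            for s, e in sorted(tx.cds):
                lines.append(row("CDS", s, e, attrs))
        path.write_text("\n".join(lines) + "\n")

    def write_fasta(self, path: Path) -> None:
        with open(path, "w") as fh:
            for name in sorted(self.genome):
                fh.write(f">{name}\n")
                seq = self.genome[name]
                for i in range(0, len(seq), 80):
                    fh.write(seq[i:i + 80] + "\n")

    def write_registry(self, path: Path) -> None:
        rows = ["symbol\tdomain_start_aa\tdomain_end_aa\tdomain_name"]
        for name in self.config.kinase_genes:
            sg = self.genes[name]
            plen = sg.cds_len // 3 - 1
            c2aa = sg.exon_t_lens[1] // 3
            start = max(2, c2aa // 2)
            end = plen - 5
            rows.append(f"{name}\t{start}\t{end}\tPkinase")
        path.write_text("\n".join(rows) + "\n")


def simulate_annotation(config: SimConfig) -> SimulatedAnnotation:
    """Generate the gene set and genome for a configuration (deterministic
    for a given seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    names = config.gene_names()
    special = {g for pf in config.planted_fusions for g in (pf.gene5, pf.gene3)}
    special |= set(config.kinase_genes)
    homolog_of = {b: a for a, b in config.artifact_spec.homolog_pairs}

    builders = {"chrS1": _ChromBuilder("chrS1"), "chrS2": _ChromBuilder("chrS2")}
    genes: dict[str, SimGene] = {}
    for i, name in enumerate(names):
        template = genes.get(homolog_of.get(name, ""))
        if name in homolog_of and template is None:
            raise ValueError(f"homolog template for {name} must precede it")
        n_exons = int(rng.integers(4, 7)) if name in special else int(rng.integers(2, 7))
        sg = _make_gene(rng, name, n_exons, template=template,
                        mutation_rate=config.artifact_spec.homolog_mutation_rate)
        strand = "+" if rng.random() < 0.5 else "-"
        _place_gene(rng, builders["chrS1" if i % 2 == 0 else "chrS2"], sg, strand)
        genes[name] = sg
    for b in builders.values():
        b.append(_rand_seq(rng, 1000))
    genome = {name: b.sequence() for name, b in builders.items()}
    return SimulatedAnnotation(config=config, genes=genes, genome=genome)


# ---------------------------------------------------------------------------
# evidence generation
# ---------------------------------------------------------------------------

def _junction(pf: PlantedFusion, g5: SimGene, g3: SimGene) -> tuple[int, int, int, int]:
    """(t_donor, t_acceptor, donor_g, acceptor_g) for a planted fusion."""
    if pf.frame_intent == "promoter":
        t_donor = g5.exon_t_lens[0] - 1
    else:
        t_donor = g5.exon_t_start(3) - 1  # last base of exon 2
        if pf.frame_intent == "out_of_frame":
            t_donor -= 1  # cryptic donor, shifts the frame by construction
    t_acc = g3.exon_t_start(pf.acceptor_exon)
    return t_donor, t_acc, g5.tpos_to_genomic(t_donor), g3.tpos_to_genomic(t_acc)


def _t_locus(sg: SimGene, t0: int, t1: int) -> Locus:
    """Locus of a transcript-coordinate window lying within a single exon."""
    a, b = sg.tpos_to_genomic(t0), sg.tpos_to_genomic(t1 - 1)
    start = min(a, b)
    return Locus(chrom=sg.chrom, start=start, strand=sg.strand, span=t1 - t0)


def _flip(locus: Locus) -> Locus:
    return Locus(locus.chrom, locus.start, "-" if locus.strand == "+" else "+",
                 locus.span)


def _fusion_records(rng: np.random.Generator, sample: str, pf: PlantedFusion,
                    g5: SimGene, g3: SimGene) -> list[ChimericEvidence]:
    records: list[ChimericEvidence] = []
    tag = f"{g5.symbol}-{g3.symbol}-{sample}"
    has_junction = pf.n_split > 0
    if has_junction:
        t_donor, t_acc, donor_g, acceptor_g = _junction(pf, g5, g3)
    else:  # trans-splicing chimeras have no resolvable junction
        t_donor = g5.exon_t_start(2) + 80
        t_acc = g3.exon_t_start(2) + 20

    for i in range(pf.n_split):
        oh5 = 18 + (i * 3) % 9
        oh3 = 16 + (i * 5) % 11
        locus_a = _t_locus(g5, t_donor - oh5 + 1, t_donor + 1)
        locus_b = _t_locus(g3, t_acc, t_acc + oh3)
        rec = ChimericEvidence(sample, f"{tag}:sp{i}", "split", locus_a, locus_b,
                               donor_g, acceptor_g, oh5, oh3)
        if i % 3 == 2:  # antisense representation of the same fragment
            rec = ChimericEvidence(sample, rec.read_id, "split",
                                   _flip(locus_b), _flip(locus_a),
                                   acceptor_g, donor_g, oh3, oh5)
        records.append(rec)
    for i in range(pf.n_chimeric):
        j5 = int(rng.integers(0, 30))
        j3 = int(rng.integers(0, 30))
        locus_a = _t_locus(g5, t_donor + 1 - 40 - j5, t_donor + 1 - j5)
        locus_b = _t_locus(g3, t_acc + j3, t_acc + j3 + 40)
        rec = ChimericEvidence(sample, f"{tag}:pr{i}", "pair", locus_a, locus_b)
        if i % 3 == 2:
            rec = ChimericEvidence(sample, rec.read_id, "pair",
                                   _flip(locus_b), _flip(locus_a))
        records.append(rec)
    return records


def _noise_records(rng: np.random.Generator, sample: str, config: SimConfig,
                   genes: dict[str, SimGene],
                   excluded: set[frozenset[str]]) -> list[ChimericEvidence]:
    names = config.gene_names()
    records = []
    pairs = [(a, b) for a in names for b in names if a != b]
    counts = rng.poisson(config.noise, size=len(pairs))
    for (a, b), k in zip(pairs, counts):
        if k == 0 or frozenset((a, b)) in excluded:
            continue
        ga, gb = genes[a], genes[b]
        for i in range(min(int(k), 3)):
            ta = ga.exon_t_start(2) + int(rng.integers(0, 40))
            tb = gb.exon_t_start(2) + int(rng.integers(0, 40))
            records.append(ChimericEvidence(
                sample, f"bg-{a}-{b}-{sample}:{i}", "pair",
                _t_locus(ga, ta, ta + 40), _t_locus(gb, tb, tb + 40)))
    return records


@dataclass
class SimulationResult:
    config: SimConfig
    annotation: SimulatedAnnotation
    outdir: Path
    paths: dict[str, Path]
    truth: dict


def simulate_cohort(config: SimConfig, outdir: str | Path) -> SimulationResult:
    """Generate and write the complete synthetic cohort.

    Outputs: ``annotation.gtf``, ``genome.fa``, ``kinases.tsv``,
    ``expression.tsv``, ``samples.tsv`` (sample_id, cohort, evidence path),
    ``evidence/<sample>.tsv``, ``normals/<normal>.tsv`` and ``truth.json``
    (the planted ground truth, including the expected driver set).
    """
    config.validate()
    outdir = Path(outdir)
    (outdir / "evidence").mkdir(parents=True, exist_ok=True)
    (outdir / "normals").mkdir(parents=True, exist_ok=True)

    sim = simulate_annotation(config)
    rng = np.random.default_rng(config.seed + 1)

    samples = [f"TUMOR{i:02d}" for i in range(1, config.n_samples + 1)]
    normals = [f"NORMAL{i:02d}" for i in range(1, config.n_normals + 1)]
    planted_pairs = {frozenset((pf.gene5, pf.gene3)) for pf in config.planted_fusions}

    # choose carriers
    carriers: dict[PlantedFusion, list[str]] = {}
    for pf in config.planted_fusions:
        k = max(1, round(pf.prevalence * config.n_samples)) if pf.prevalence else 0
        chosen = rng.choice(config.n_samples, size=k, replace=False)
        carriers[pf] = [samples[i] for i in sorted(chosen)]

    # tumour evidence
    records_by_sample: dict[str, list[ChimericEvidence]] = {s: [] for s in samples}
    for pf in config.planted_fusions:
        g5, g3 = sim.genes[pf.gene5], sim.genes[pf.gene3]
        for s in carriers[pf]:
            records_by_sample[s].extend(_fusion_records(rng, s, pf, g5, g3))
    for s in samples:
        records_by_sample[s].extend(
            _noise_records(rng, s, config, sim.genes, planted_pairs))

    # normals evidence: planted normals artifacts plus background
    normal_records: dict[str, list[ChimericEvidence]] = {n: [] for n in normals}
    n_carry = min(config.artifact_spec.n_normals_carrying, config.n_normals)
    for pf in config.planted_fusions:
        if pf.role != "normals_artifact":
            continue
        g5, g3 = sim.genes[pf.gene5], sim.genes[pf.gene3]
        for n in normals[:n_carry]:
            normal_records[n].extend(_fusion_records(rng, n, pf, g5, g3))
    for n in normals:
        normal_records[n].extend(
            _noise_records(rng, n, config, sim.genes, planted_pairs))

    # expression: log-normal FPKM-like values, trans-splice partner inflated
    # in the first carrying sample only
    gene_names = config.gene_names()
    base = np.exp(rng.normal(1.5, 0.6, size=len(gene_names)))
    values = base[:, None] * np.exp(rng.normal(0.0, 0.3,
                                               size=(len(gene_names), len(samples))))
    for pf in config.planted_fusions:
        if pf.role == "trans_splice" and carriers[pf]:
            col = samples.index(carriers[pf][0])
            for g in (pf.gene5, pf.gene3):
                values[gene_names.index(g), col] *= config.artifact_spec.trans_splice_fold

    # ---- write everything -------------------------------------------------
    paths = {
        "gtf": outdir / "annotation.gtf",
        "fasta": outdir / "genome.fa",
        "registry": outdir / "kinases.tsv",
        "expression": outdir / "expression.tsv",
        "sample_sheet": outdir / "samples.tsv",
        "evidence_dir": outdir / "evidence",
        "normals_dir": outdir / "normals",
        "truth": outdir / "truth.json",
    }
    sim.write_gtf(paths["gtf"])
    sim.write_fasta(paths["fasta"])
    sim.write_registry(paths["registry"])
    with open(paths["expression"], "w") as fh:
        fh.write("gene\t" + "\t".join(samples) + "\n")
        for gi, g in enumerate(gene_names):
            fh.write(g + "\t" + "\t".join(f"{values[gi, si]:.4f}"
                                          for si in range(len(samples))) + "\n")
    with open(paths["sample_sheet"], "w") as fh:
        fh.write("sample_id\tcohort\tevidence\n")
        for s in samples:
            fh.write(f"{s}\t{config.cohort}\tevidence/{s}.tsv\n")
    for s in samples:
        write_evidence(outdir / "evidence" / f"{s}.tsv", records_by_sample[s])
    for n in normals:
        write_evidence(outdir / "normals" / f"{n}.tsv", normal_records[n])

    fusion_truth = []
    for pf in config.planted_fusions:
        entry = asdict(pf)
        entry["carriers"] = carriers[pf]
        if pf.n_split > 0:
            g5, g3 = sim.genes[pf.gene5], sim.genes[pf.gene3]
            _, _, donor_g, acceptor_g = _junction(pf, g5, g3)
            entry["breakpoint5"] = donor_g + 1
            entry["breakpoint3"] = acceptor_g + 1
        fusion_truth.append(entry)
    truth = {
        "seed": config.seed,
        "cohort": config.cohort,
        "samples": samples,
        "normals": normals,
        "fusions": fusion_truth,
        "driver_pairs": sorted([pf.gene5, pf.gene3]
                               for pf in config.planted_fusions
                               if pf.role == "driver"),
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return SimulationResult(config=config, annotation=sim, outdir=outdir,
                            paths=paths, truth=truth)
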