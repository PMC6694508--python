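"""Synthetic allopolyploid small-RNA study generator.

Builds the full input set the analysis consumes, with known ground truth:

* three genomes — parent 1 (subgenomes An + Cn), parent 2 (Ar, derived from
  An by per-site divergence), and a triploid F1 (An + Ar + Cn) with a
  configurable fraction of parental miRNA loci deleted and novel loci
  inserted;
* GFF3 annotations of protein-coding genes and planted miRNA loci, with at
  least five coding genes on each side of every miRNA (the neighbourhood the
  synteny analysis relies on);
* a known-mature-miRNA FASTA (miRBase-style headers) and a structural-ncRNA
  contaminant FASTA;
* negative-binomial expression with a configurable non-additive fraction
  relative to the mid-parent value, and FASTQ libraries whose read-length
  mode is 24 nt, with adapter read-through, sequencing error and ncRNA
  contamination.

Precursors are built constructively (5' arm containing the mature, short
loop, reverse complement of the arm) so hairpin validity holds by
construction rather than by rejection sampling.  All randomness flows from a
single Generator seeded by ``config.seed``; equal seeds give byte-identical
output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from polymir.config import SimulationConfig
from polymir.io import revcomp, write_fasta, write_fastq, write_gff3, GFF_COLUMNS

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# mixture over locus homes: shared A (both parents), An-only, Ar-only, Cn-only
_HOME_PROBS = {"sharedA": 0.55, "An": 0.10, "Ar": 0.10, "Cn": 0.25}

_KNOWN_FAMILIES = [
    "miR156", "miR159", "miR160", "miR166", "miR167", "miR171_1", "miR172",
    "miR319", "miR390", "miR395", "miR396", "miR399", "miR408", "miR827",
]
_SPECIES = ["ath", "bna", "bra", "osa"]


class CapacityError(ValueError):
    """Raised when the configured genome cannot host the requested loci."""


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


def _mutate(seq: str, rng: np.random.Generator, rate: float) -> str:
    codes = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.flatnonzero(rng.random(codes.shape[0]) < rate)
    if hit.size:
        # shift by 1-3 in base space: always a different base
        idx = np.searchsorted(_BASES, codes[hit])
        codes[hit] = _BASES[(idx + rng.integers(1, 4, hit.size)) % 4]
    return codes.tobytes().decode()


def _mutate_k(seq: str, rng: np.random.Generator, k: int) -> str:
    if k == 0:
        return seq
    pos = rng.choice(len(seq), size=k, replace=False)
    codes = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    idx = np.searchsorted(_BASES, codes[pos])
    codes[pos] = _BASES[(idx + rng.integers(1, 4, k)) % 4]
    return codes.tobytes().decode()


def build_precursor(
    mature: str, rng: np.random.Generator, pad5: int = 4, pad3: int = 8, loop: int = 6
) -> tuple[str, int]:
    """Constructive hairpin: arm + loop + revcomp(arm), mature on the 5' arm.

    Returns (precursor, mature offset).  Every base of the mature pairs with
    the 3' arm, so the hairpin acceptance criteria hold by construction.
    """
    arm = _random_seq(rng, pad5) + mature + _random_seq(rng, pad3)
    return arm + _random_seq(rng, loop) + revcomp(arm), pad5


@dataclass
class SimulationTruth:
    """Ground truth of the planted study: one row per simulated miRNA.

    ``loci`` columns: mirna_id, mature, identity (conserved/novel), known_id,
    home (sharedA/An/Ar/Cn), chrom, strand, precursor_start/end and
    mature_start/end (0-based half-open, identical on homologous chromosome
    copies), membership flags in_parent1/in_parent2/in_f1, synteny_status
    (syntenic/lost_in_f1/gained_in_f1), expression_class (additive /
    nonadditive_up / nonadditive_down / not_applicable), pattern_class (down
    calls only), and true per-sample means mean_parent1/mean_parent2/mean_f1
    on the common abundance scale.
    """

    loci: pd.DataFrame

    @property
    def lost_ids(self) -> list[str]:
        return list(self.loci.loc[self.loci.synteny_status == "lost_in_f1", "mirna_id"])

    @property
    def gained_ids(self) -> list[str]:
        return list(self.loci.loc[self.loci.synteny_status == "gained_in_f1", "mirna_id"])

    def means(self) -> pd.DataFrame:
        m = self.loci.set_index("mirna_id")[["mean_parent1", "mean_parent2", "mean_f1"]]
        m.columns = ["parent1", "parent2", "f1"]
        return m


@dataclass
class Simulation:
    """Genomes, annotations, reference sets and truth for one simulated study."""

    config: SimulationConfig
    genomes: dict[str, dict[str, str]]
    annotations: dict[str, pd.DataFrame]
    known_mature: dict[str, str]
    ncrna: dict[str, str]
    truth: SimulationTruth


def _make_known_set(rng: np.random.Generator) -> dict[str, str]:
    """miRBase-style reference matures: a few variants per family."""
    known: dict[str, str] = {}
    for fam in _KNOWN_FAMILIES:
        base = _random_seq(rng, int(rng.integers(20, 23)))
        n_var = int(rng.integers(2, 5))
        for v in range(n_var):
            letter = "abcd"[v]
            species = _SPECIES[int(rng.integers(0, len(_SPECIES)))]
            arm = ["", "-5p", "-3p"][int(rng.integers(0, 3))]
            name = f"{species}-{fam}{letter}{arm}"
            known[name] = _mutate_k(base, rng, int(rng.integers(0, 4)))
    return known


def _make_ncrna_set(rng: np.random.Generator) -> dict[str, str]:
    """Rfam-style structural ncRNA contaminants."""
    classes = [("rRNA", 4, 1500), ("tRNA", 6, 75), ("snRNA", 4, 150), ("snoRNA", 4, 120)]
    out: dict[str, str] = {}
    for cls, n, length in classes:
        for i in range(n):
            out[f"{cls}_{i + 1}"] = _random_seq(rng, length)
    return out


def _gene_layout(cfg: SimulationConfig) -> tuple[list[tuple[int, int]], dict[int, int]]:
    """Evenly spaced gene coordinates and the miRNA-capable gap centres.

    Returns (gene spans, {gap index after gene k: gap centre}).  A gap
    qualifies for a miRNA only if >=5 genes lie on each side.
    """
    n = cfg.n_coding_genes_per_chrom
    slot = cfg.chrom_length / (n + 1)
    if slot - cfg.gene_length < 320:
        raise CapacityError(
            "intergenic gaps too small to host miRNA precursors; "
            "increase chrom_length or reduce n_coding_genes_per_chrom"
        )
    genes = []
    for g in range(n):
        start = int(round(slot * (g + 1) - cfg.gene_length / 2))
        genes.append((start, start + cfg.gene_length))
    gaps = {}
    for k in range(4, n - 5):
        centre = (genes[k][1] + genes[k + 1][0]) // 2
        gaps[k] = centre
    return genes, gaps


def _min_offset_distance(a: str, b: str) -> int:
    """Best ungapped offset distance; overhanging bases count as mismatches."""
    best = len(a) + len(b)
    for s in range(-(len(b) - 1), len(a)):
        ov = min(len(a), s + len(b)) - max(0, s)
        if ov <= 0:
            continue
        mm = sum(1 for i in range(max(0, s), min(len(a), s + len(b))) if a[i] != b[i - s])
        d = mm + (len(a) - ov) + (len(b) - ov)
        best = min(best, d)
    return best


def simulate_genomes(config: SimulationConfig) -> Simulation:
    """Generate the three genomes, annotations, reference sets and truth."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    known = _make_known_set(rng)
    ncrna = _make_ncrna_set(rng)
    known_seqs = list(known.items())

    nchrom = cfg.n_chrom_per_subgenome
    an = {f"An{i + 1}": _random_seq(rng, cfg.chrom_length) for i in range(nchrom)}
    cn = {f"Cn{i + 1}": _random_seq(rng, cfg.chrom_length) for i in range(nchrom)}
    ar = {
        f"Ar{i + 1}": _mutate(an[f"An{i + 1}"], rng, cfg.parental_divergence)
        for i in range(nchrom)
    }

    genes, gaps = _gene_layout(cfg)
    # gap pool: A-space (shared coordinates between An and Ar) and C-space
    pool = [("A", c, k) for c in range(nchrom) for k in gaps] + [
        ("C", c, k) for c in range(nchrom) for k in gaps
    ]
    n_a_gaps = nchrom * len(gaps)

    homes = rng.choice(
        list(_HOME_PROBS), size=cfg.n_mirna_loci, p=list(_HOME_PROBS.values())
    )
    n_a_needed = int(np.sum(homes != "Cn"))
    n_c_needed = int(np.sum(homes == "Cn"))
    if n_a_needed > n_a_gaps or n_c_needed > n_a_gaps:
        raise CapacityError(
            f"{cfg.n_mirna_loci} miRNA loci exceed the "
            f"{n_a_gaps} qualifying intergenic gaps per genome space"
        )
    a_slots = [p for p in pool if p[0] == "A"]
    c_slots = [p for p in pool if p[0] == "C"]
    a_pick = list(rng.permutation(len(a_slots))[: n_a_needed + cfg.f1_gain_count])
    c_pick = list(rng.permutation(len(c_slots))[:n_c_needed])
    if len(a_pick) < n_a_needed + cfg.f1_gain_count:
        raise CapacityError("not enough free gaps for f1_gain_count insertions")

    n_conserved = int(round(cfg.conserved_fraction * cfg.n_mirna_loci))
    identity = np.array(["conserved"] * n_conserved + ["novel"] * (cfg.n_mirna_loci - n_conserved))
    identity = identity[rng.permutation(cfg.n_mirna_loci)]

    matures: list[str] = []

    def _novel_mature() -> str:
        while True:
            m = _random_seq(rng, int(rng.integers(cfg.mature_len_range[0], cfg.mature_len_range[1] + 1)))
            if all(_min_offset_distance(m, ks) > 2 for _, ks in known_seqs) and m not in matures:
                return m

    rows = []
    ai = ci = 0
    chrom_sets = {"parent1": {**an, **cn}, "parent2": dict(ar), "f1": {}}

    def _plant(chroms: dict[str, str], name: str, start: int, frag: str) -> None:
        s = chroms[name]
        chroms[name] = s[:start] + frag + s[start + len(frag):]

    for li in range(cfg.n_mirna_loci):
        home = homes[li]
        if home == "Cn":
            _, cidx, k = c_slots[c_pick[ci]]
            ci += 1
            chrom = f"Cn{cidx + 1}"
        else:
            _, cidx, k = a_slots[a_pick[ai]]
            ai += 1
            chrom = f"{'Ar' if home == 'Ar' else 'An'}{cidx + 1}"
        centre = gaps[k]
        if identity[li] == "conserved":
            while True:  # matures identify miRNA entities, so keep them unique
                kid, kseq = known_seqs[int(rng.integers(0, len(known_seqs)))]
                mature = _mutate_k(kseq, rng, int(rng.integers(0, 3)))
                if mature not in matures:
                    break
            known_id = kid
        else:
            mature = _novel_mature()
            known_id = ""
        matures.append(mature)
        pre, moff = build_precursor(mature, rng)
        start = centre - len(pre) // 2
        strand = "+" if rng.random() < 0.5 else "-"
        frag = pre if strand == "+" else revcomp(pre)
        if home == "sharedA":
            _plant(chrom_sets["parent1"], chrom, start, frag)
            _plant(chrom_sets["parent2"], f"Ar{cidx + 1}", start, frag)
        elif home == "An" or home == "Cn":
            _plant(chrom_sets["parent1"], chrom, start, frag)
        else:  # Ar only
            _plant(chrom_sets["parent2"], chrom, start, frag)
        if strand == "+":
            ms, me = start + moff, start + moff + len(mature)
        else:
            me = start + len(pre) - moff
            ms = me - len(mature)
        rows.append(
            dict(
                mirna_id=f"mir{li + 1:03d}",
                mature=mature,
                identity=identity[li],
                known_id=known_id,
                home=home,
                chrom=chrom,
                strand=strand,
                precursor_start=start,
                precursor_end=start + len(pre),
                mature_start=ms,
                mature_end=me,
                in_parent1=home in ("sharedA", "An", "Cn"),
                in_parent2=home in ("sharedA", "Ar"),
                in_f1=True,
                synteny_status="syntenic",
            )
        )

    # F1 inherits both parental chromosome sets
    chrom_sets["f1"] = {**chrom_sets["parent1"], **chrom_sets["parent2"]}

    # losses: excise the precursor from every F1 copy, preserving coordinates
    n_lost = int(round(cfg.f1_loss_fraction * cfg.n_mirna_loci))
    lost_idx = rng.choice(cfg.n_mirna_loci, size=n_lost, replace=False) if n_lost else []
    for li in sorted(int(i) for i in np.atleast_1d(lost_idx)):
        r = rows[li]
        length = r["precursor_end"] - r["precursor_start"]
        filler = _random_seq(rng, length)
        copies = [r["chrom"]]
        if r["home"] == "sharedA":
            copies.append(r["chrom"].replace("An", "Ar"))
        for name in copies:
            _plant(chrom_sets["f1"], name, r["precursor_start"], filler)
        r["in_f1"] = False
        r["synteny_status"] = "lost_in_f1"

    # gains: brand-new hairpins in free A-space gaps of the F1
    for gi in range(cfg.f1_gain_count):
        _, cidx, k = a_slots[a_pick[n_a_needed + gi]]
        sub = "An" if gi % 2 == 0 else "Ar"
        chrom = f"{sub}{cidx + 1}"
        centre = gaps[k]
        mature = _novel_mature()
        matures.append(mature)
        pre, moff = build_precursor(mature, rng)
        start = centre - len(pre) // 2
        strand = "+" if rng.random() < 0.5 else "-"
        _plant(chrom_sets["f1"], chrom, start, pre if strand == "+" else revcomp(pre))
        if strand == "+":
            ms, me = start + moff, start + moff + len(mature)
        else:
            me = start + len(pre) - moff
            ms = me - len(mature)
        rows.append(
            dict(
                mirna_id=f"mir{cfg.n_mirna_loci + gi + 1:03d}",
                mature=mature,
                identity="novel",
                known_id="",
                home=sub,
                chrom=chrom,
                strand=strand,
                precursor_start=start,
                precursor_end=start + len(pre),
                mature_start=ms,
                mature_end=me,
                in_parent1=False,
                in_parent2=False,
                in_f1=True,
                synteny_status="gained_in_f1",
            )
        )

    truth_df = pd.DataFrame(rows)
    _assign_expression_truth(truth_df, cfg, rng)

    annotations = {
        g: _build_annotation(g, chrom_sets[g], genes, truth_df, cfg)
        for g in ("parent1", "parent2", "f1")
    }
    return Simulation(
        config=cfg,
        genomes=chrom_sets,
        annotations=annotations,
        known_mature=known,
        ncrna=ncrna,
        truth=SimulationTruth(truth_df),
    )


def _assign_expression_truth(df: pd.DataFrame, cfg: SimulationConfig, rng: np.random.Generator) -> None:
    """True per-sample mean abundances and additive / non-additive classes."""
    n = len(df)
    b1 = np.exp(rng.uniform(np.log(5.0), np.log(500.0), n))
    b2 = np.exp(rng.uniform(np.log(5.0), np.log(500.0), n))
    b1[~df.in_parent1.to_numpy()] = 0.0
    b2[~df.in_parent2.to_numpy()] = 0.0
    mpv = (b1 + b2) / 2.0
    f1 = mpv.copy()
    cls = np.array(["additive"] * n, dtype=object)
    eligible = np.flatnonzero(df.in_f1.to_numpy() & ((b1 > 0) | (b2 > 0)))
    k = int(round(cfg.nonadditive_fraction * eligible.size))
    chosen = rng.choice(eligible, size=k, replace=False) if k else np.array([], dtype=int)
    up = rng.random(chosen.size) < 0.5
    for idx, is_up in zip(chosen, up):
        f1[idx] = mpv[idx] * 2.0 ** (cfg.nonadditive_log2fc if is_up else -cfg.nonadditive_log2fc)
        cls[idx] = "nonadditive_up" if is_up else "nonadditive_down"
    gained = df.synteny_status.to_numpy() == "gained_in_f1"
    f1[gained] = np.exp(rng.uniform(np.log(5.0), np.log(500.0), int(gained.sum())))
    cls[gained] = "not_applicable"
    lost = ~df.in_f1.to_numpy()
    f1[lost] = 0.0
    cls[lost] = "not_applicable"

    c = 0.5
    with np.errstate(divide="ignore"):
        ratio = np.log2((b1 + c) / (b2 + c))
    pattern = np.where(ratio > 1, "parent1_higher", np.where(ratio < -1, "parent2_higher", "equal"))
    df["expression_class"] = cls
    df["pattern_class"] = np.where(cls == "nonadditive_down", pattern, "")
    df["mean_parent1"] = b1
    df["mean_parent2"] = b2
    df["mean_f1"] = f1


def _build_annotation(
    genome: str,
    chroms: dict[str, str],
    genes: list[tuple[int, int]],
    truth: pd.DataFrame,
    cfg: SimulationConfig,
) -> pd.DataFrame:
    rows = []
    for chrom in chroms:
        for g, (s, e) in enumerate(genes):
            gid = f"{genome}_{chrom}_g{g + 1:03d}"
            rows.append(
                (chrom, "polymir_sim", "gene", s + 1, e, ".", "+", ".",
                 f"ID={gid};biotype=protein_coding")
            )
    member = {"parent1": "in_parent1", "parent2": "in_parent2", "f1": "in_f1"}[genome]
    for r in truth.itertuples(index=False):
        if not getattr(r, member):
            continue
        copies = [r.chrom]
        if r.home == "sharedA" and genome != "parent1":
            copies = [r.chrom.replace("An", "Ar")] if genome == "parent2" else [r.chrom, r.chrom.replace("An", "Ar")]
        for chrom in copies:
            rows.append(
                (chrom, "polymir_sim", "miRNA", r.mature_start + 1, r.mature_end,
                 ".", r.strand, ".", f"ID={r.mirna_id};Name={r.mirna_id}")
            )
    df = pd.DataFrame(rows, columns=GFF_COLUMNS)
    df["feature_id"] = df["attributes"].str.extract(r"ID=([^;]+)")[0]
    return df.sort_values(["seqid", "start"], kind="stable").reset_index(drop=True)


def simulate_expression(truth: SimulationTruth, config: SimulationConfig) -> pd.DataFrame:
    """Negative-binomial per-replicate true counts around class-determined means.

    Returns a DataFrame indexed by mirna_id with one column per library
    ("<sample>_rep<k>"); counts are drawn NB(mean mu, variance
    mu + dispersion * mu^2), Poisson in the dispersion -> 0 limit.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed + 1)
    means = truth.means()
    cols = {}
    for sample in ("parent1", "parent2", "f1"):
        mu = means[sample].to_numpy(dtype=float)
        for rep in range(1, cfg.n_replicates + 1):
            cols[f"{sample}_rep{rep}"] = _nb_draw(mu, cfg.nb_dispersion, rng)
    return pd.DataFrame(cols, index=means.index)


def _nb_draw(mu: np.ndarray, dispersion: float, rng: np.random.Generator) -> np.ndarray:
    out = np.zeros(mu.shape[0], dtype=np.int64)
    pos = mu > 0
    if dispersion <= 1e-12:
        out[pos] = rng.poisson(mu[pos])
    else:
        size = 1.0 / dispersion
        p = size / (size + mu[pos])
        out[pos] = rng.negative_binomial(size, p)
    return out


def simulate_reads(
    sim: Simulation, expression: pd.DataFrame, config: SimulationConfig | None = None
) -> dict[str, list[tuple[str, str, str]]]:
    """Sequence each library: miRNA reads, 24-nt genomic background, ncRNA.

    Per library, ``mean_depth`` read slots split binomially into contaminant
    and background shares; the remainder samples miRNA matures multinomially
    in proportion to that library's true counts (so the negative-binomial
    between-replicate variation survives in the sequenced counts).  A
    configurable fraction of reads carries the 3' adapter; qualities are
    constant Phred 35.  Returns {library: [(id, seq, qual), ...]}.
    """
    cfg = config or sim.config
    rng = np.random.default_rng(cfg.seed + 2)
    truth = sim.truth.loci
    matures = truth.set_index("mirna_id")["mature"]
    genome_of = {"parent1": "parent1", "parent2": "parent2", "f1": "f1"}
    ncrna_seqs = list(sim.ncrna.values())
    libraries: dict[str, list[tuple[str, str, str]]] = {}
    for lib in expression.columns:
        sample = lib.rsplit("_rep", 1)[0]
        chroms = sim.genomes[genome_of[sample]]
        chrom_names = sorted(chroms)
        reads: list[str] = []
        n_contam = int(rng.binomial(cfg.mean_depth, cfg.contaminant_fraction))
        n_bg = int(rng.binomial(cfg.mean_depth, cfg.background_24nt_fraction))
        n_mir = cfg.mean_depth - n_contam - n_bg
        counts = expression[lib].to_numpy(dtype=float)
        if counts.sum() > 0 and n_mir > 0:
            draw = rng.multinomial(n_mir, counts / counts.sum())
        else:
            draw = np.zeros(len(counts), dtype=int)
        for mid, c in zip(expression.index, draw):
            if c:
                reads.extend(_mirna_reads(matures[mid], int(c), cfg.error_rate, rng))
        for _ in range(n_bg):
            chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
            seq = chroms[chrom]
            pos = int(rng.integers(0, len(seq) - 24))
            w = seq[pos : pos + 24]
            reads.append(w if rng.random() < 0.5 else revcomp(w))
        for _ in range(n_contam):
            src = ncrna_seqs[int(rng.integers(0, len(ncrna_seqs)))]
            ln = int(rng.integers(18, 31))
            pos = int(rng.integers(0, max(1, len(src) - ln)))
            reads.append(src[pos : pos + ln])
        order = rng.permutation(len(reads))
        with_adapter = rng.random(len(reads)) < cfg.adapter_fraction
        records = []
        for out_i, ri in enumerate(order):
            seq = reads[ri]
            if with_adapter[ri]:
                seq = seq + cfg.adapter_seq
            records.append((f"{lib}_{out_i + 1:07d}", seq, "D" * len(seq)))
        libraries[lib] = records
    return libraries


def _mirna_reads(mature: str, count: int, error_rate: float, rng: np.random.Generator) -> list[str]:
    reads = [mature] * count
    if error_rate > 0:
        L = len(mature)
        n_err = int(rng.binomial(count * L, error_rate))
        for _ in range(n_err):
            ri = int(rng.integers(0, count))
            pos = int(rng.integers(0, L))
            s = reads[ri]
            old = s[pos]
            new = "ACGT"[(("ACGT".index(old) if old in "ACGT" else 0) + int(rng.integers(1, 4))) % 4]
            reads[ri] = s[:pos] + new + s[pos + 1:]
    return reads


def write_simulation(sim: Simulation, outdir: str | Path) -> None:
    """Write genomes, annotations, reference sets, truth and config to disk."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for g in ("parent1", "parent2", "f1"):
        write_fasta(sim.genomes[g], out / f"{g}.fa")
        write_gff3(sim.annotations[g][GFF_COLUMNS], out / f"{g}.gff3")
    write_fasta(sim.known_mature, out / "known_mature.fa")
    write_fasta(sim.ncrna, out / "ncrna.fa")
    sim.truth.loci.to_csv(out / "truth_loci.tsv", sep="\t", index=False)
    sim.config.to_yaml(out / "config.yaml")


def write_libraries(libraries: dict[str, list[tuple[str, str, str]]], outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for lib, records in libraries.items():
        write_fastq(records, out / f"{lib}.fastq")
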