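"""Synthetic small-RNA experiment with planted ground truth.

The simulator emulates the data a 3-condition (control / low-temperature /
nitric-oxide donor), 3-replicate pollen-tube small-RNA-seq experiment
produces: a toy genome carrying planted miRNA hairpin loci on both strands,
a mature-miRNA catalogue with family structure, a contaminant ncRNA
catalogue, raw FASTQ libraries with adapter/polyA/low-quality/contaminant
read classes and negative-binomial tag counts, a transcriptome with target
sites planted at controlled complementarity scores, a gene->term annotation
with one designed enriched term, and qPCR Ct tables consistent with the
planted expression shifts.

Every planted non-decoy hairpin is verified at generation time to pass all
novel-miRNA criteria, and every decoy to fail exactly its designated
criterion; designs are redrawn (deterministically under the seed) until
the contract holds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .seqio import revcomp, write_fasta, write_fastq, write_gff3

_BACKGROUND_LEN_PMF = {24: 0.40, 21: 0.24, 22: 0.10, 23: 0.08, 20: 0.06,
                       19: 0.04, 18: 0.02, 25: 0.02, 26: 0.015, 27: 0.01,
                       28: 0.01, 29: 0.005, 30: 0.01}

DECOY_CLASSES = ("no_hairpin", "mature_in_loop", "shifted_star",
                 "big_bulge", "weak_energy", "low_support")

# Planted per-condition effect patterns, cycled over the planted miRNAs.
# Values scale the configured effect size; `0.4` plants a near-threshold
# shift (|log2FC| = 0.8 at the default effect of 2) that must NOT be
# called differentially expressed.
_EFFECT_PATTERNS = (
    {},                             # null
    {"LT": +1.0},                   # LT up
    {"LT": -1.0},                   # LT down
    {"NO": +1.0},
    {"NO": -1.0},
    {"LT": +1.0, "NO": +1.0},       # co-regulated, concordant
    {"LT": -1.0, "NO": -1.0},
    {"LT": +1.0, "NO": -1.0},       # co-regulated, discordant
    {"LT": +0.4},                   # near-threshold
    {},
)


@dataclass
class SimConfig:
    """Study-design parameters of the simulated experiment."""

    seed: int = 1
    conditions: tuple[str, ...] = ("CK", "LT", "NO")
    n_replicates: int = 3
    reads_per_library: int = 100_000
    genome_length: int = 30_000
    n_planted_known: int = 30
    n_planted_novel: int = 15
    n_decoy_hairpins: int = 6
    adapter_seq: str = "TGGAATTCTCGGGTGCCAAGG"
    frac_adapter_dimer: float = 0.05
    frac_polyA: float = 0.05
    frac_lowq: float = 0.05
    frac_contaminant: float = 0.10
    dispersion: float = 0.1
    effect_log2fc: float = 2.0
    known_abundance_range: tuple[float, float] = (50.0, 2000.0)
    novel_abundance_range: tuple[float, float] = (20.0, 200.0)
    n_background_tags: int = 2000
    frac_background_mapped: float = 0.15
    n_genes: int = 60
    transcript_length: int = 500
    gzip_fastq: bool = False
    backend: str = "vienna"

    def validate(self) -> None:
        junk = (self.frac_adapter_dimer + self.frac_polyA + self.frac_lowq
                + self.frac_contaminant)
        if not 0 <= junk < 1:
            raise ValueError("junk read fractions must sum to < 1")
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates per condition")
        if self.n_decoy_hairpins > len(DECOY_CLASSES):
            raise ValueError(f"at most {len(DECOY_CLASSES)} decoy classes available")
        if "CK" not in self.conditions:
            raise ValueError("conditions must include the CK calibrator")

    @property
    def libraries(self) -> list[str]:
        return [f"{c}-{r}" for c in self.conditions
                for r in range(1, self.n_replicates + 1)]

    @property
    def junk_fracs(self) -> dict[str, float]:
        return {"adapter_dimer": self.frac_adapter_dimer,
                "polyA": self.frac_polyA,
                "lowq": self.frac_lowq,
                "contaminant": self.frac_contaminant}


@dataclass
class PlantedTarget:
    gene_id: str
    mirna_id: str
    site_start: int          # 1-based position in transcript
    designed_score: float
    designed_mode: str       # cleavage | translation_inhibition


@dataclass
class Truth:
    """Everything the simulator planted, for downstream comparison."""

    mirnas: pd.DataFrame               # one row per planted miRNA/decoy
    catalogue: list[tuple[str, str, str]]      # (id, family, mature DNA)
    contaminants: list[tuple[str, str, str]]   # (id, class, sequence)
    background: pd.DataFrame           # tag, weight, mapped
    config: SimConfig

    def planted(self, kind: str) -> pd.DataFrame:
        return self.mirnas[self.mirnas.kind == kind]


# ------------------------------------------------------------ seq utilities

def _rand_seq(rng, n: int, alphabet: str = "ACGT") -> str:
    return "".join(np.asarray(list(alphabet))[rng.integers(0, len(alphabet), n)])


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _min_family_dist(seq: str, pool: list[str]) -> int:
    dists = [_hamming(seq, p) for p in pool if len(p) == len(seq)]
    return min(dists) if dists else 99


def _canonical_precursor(rng, mature: str) -> str:
    """Mature + loop + star with canonical 2-nt 3' overhang geometry."""
    loop = _rand_seq(rng, 8, "ACT")
    return mature + loop + revcomp(mature[:-2]) + "AA"


def _draw_mature(rng, pool: list[str], length: int | None = None,
                 alphabet: str = "ACGT", min_dist: int = 5) -> str:
    """A mature sequence distinct (Hamming >= min_dist) from the pool."""
    for _ in range(500):
        n = length or int(rng.choice([20, 21, 22], p=[0.15, 0.6, 0.25]))
        seq = _rand_seq(rng, n, alphabet)
        gc = seq.count("G") + seq.count("C")
        if alphabet == "ACGT" and not 0.3 <= gc / n <= 0.7:
            continue
        if _min_family_dist(seq, pool) >= min_dist:
            return seq
    raise RuntimeError("could not draw a sufficiently distinct mature sequence")


# --------------------------------------------------- genome + truth planting

PAD_LEN = 150          # unstructured A/C spacer on each side of a locus


def _evaluate_cassette(cassette: str, m_start: int, m_len: int, strand: str,
                       backend: str):
    """Run the exact novel-caller evaluation path on a locus cassette
    (lazy import avoids a module cycle)."""
    from . import novel

    params = novel.NovelParams(backend=backend)
    region, mat = novel._extract_region(cassette,
                                        (m_start, m_start + m_len - 1),
                                        strand, params)
    return novel.evaluate_locus(region, mat, counts_total=50, params=params)


def _build_cassette(rng, pre: str, off: int, m_len: int, strand: str
                    ) -> tuple[str, int]:
    """Pad + oriented precursor + pad; returns (cassette, mature start)."""
    pad_l = _rand_seq(rng, PAD_LEN, "AC")
    pad_r = _rand_seq(rng, PAD_LEN, "AC")
    insert = pre if strand == "+" else revcomp(pre)
    if strand == "+":
        m_start = PAD_LEN + off
    else:
        m_start = PAD_LEN + len(pre) - off - m_len
    return pad_l + insert + pad_r, m_start


def _design_planted_mirna(rng, pool: list[str], backend: str, strand: str
                          ) -> tuple[str, str, str, str, int]:
    """(mature, star, precursor, cassette, mature start) — the cassette is
    verified in situ to pass every novel-miRNA criterion on its strand."""
    for _ in range(80):
        mature = _draw_mature(rng, pool)
        pre = _canonical_precursor(rng, mature)
        cassette, m_start = _build_cassette(rng, pre, 0, len(mature), strand)
        if _evaluate_cassette(cassette, m_start, len(mature), strand,
                              backend).accepted:
            return (mature, revcomp(mature[:-2]) + "AA", pre, cassette,
                    m_start)
    raise RuntimeError("failed to design a planted miRNA hairpin")


def _design_decoy(rng, cls: str, pool: list[str], backend: str, strand: str
                  ) -> tuple[str, str, str, int]:
    """(mature, precursor, cassette, mature start) failing exactly
    criterion ``cls`` when evaluated in situ."""
    expected_fail = {"no_hairpin": "hairpin", "mature_in_loop": "one_arm",
                     "shifted_star": "overhang", "big_bulge": "defects",
                     "weak_energy": "energy", "low_support": "support"}[cls]
    for _ in range(400):
        if cls == "no_hairpin":
            mature = _draw_mature(rng, pool, alphabet="AC")
            pre, off = mature, 0
        elif cls == "mature_in_loop":
            mature = _draw_mature(rng, pool)
            flank = _rand_seq(rng, 20)
            if (flank.count("G") + flank.count("C")) < 10:
                continue
            pre, off = flank + mature + revcomp(flank), 20
        elif cls == "shifted_star":
            mature = _draw_mature(rng, pool)
            loop = _rand_seq(rng, 8, "ACT")
            pre, off = mature + loop + revcomp(mature), 0   # blunt duplex
        elif cls == "big_bulge":
            mature = _draw_mature(rng, pool)
            star = revcomp(mature[:-2])
            mid = len(star) // 2
            star = star[:mid] + "A" * 6 + star[mid:]
            pre, off = mature + _rand_seq(rng, 8, "ACT") + star + "AA", 0
        elif cls == "weak_energy":
            # canonical geometry, stem weakened by spaced 1x1 mismatches
            mature = _draw_mature(rng, pool, length=21)
            k = len(mature)
            n_mm = int(rng.integers(3, 6))
            positions = np.linspace(4, k - 7, n_mm).astype(int)
            star = list(revcomp(mature[:-2]))
            for i in positions:
                star[k - 3 - i] = mature[i]          # X:X never pairs
            pre = mature + _rand_seq(rng, 8, "ACT") + "".join(star) + "AA"
            off = 0
        elif cls == "low_support":
            mature, _star, pre, cassette, m_start = _design_planted_mirna(
                rng, pool, backend, strand)
            return mature, pre, cassette, m_start
        else:  # pragma: no cover
            raise ValueError(cls)
        cassette, m_start = _build_cassette(rng, pre, off, len(mature),
                                            strand)
        call = _evaluate_cassette(cassette, m_start, len(mature), strand,
                                  backend)
        failed = [k for k, v in call.verdicts.items() if v is False]
        if not call.accepted and failed == [expected_fail]:
            return mature, pre, cassette, m_start
    raise RuntimeError(f"failed to design decoy class {cls}")


def _make_contaminants(rng) -> list[tuple[str, str, str]]:
    spec = [("rRNA_5.8S", "rRNA", 160), ("rRNA_25S_frag", "rRNA", 300),
            ("tRNA_Ala", "tRNA", 76), ("tRNA_Gly", "tRNA", 74),
            ("snRNA_U6", "snRNA", 106), ("snoRNA_R71", "snoRNA", 90),
            ("repeat_LTR1", "repeat", 250)]
    return [(name, cls, _rand_seq(rng, n)) for name, cls, n in spec]


def generate_genome(config: SimConfig) -> tuple[dict[str, str], Truth]:
    """Build the toy genome and the full planted truth set.

    Returns contigs plus a :class:`Truth` carrying the planted miRNA table
    (ids, families, sequences, loci, abundances, per-condition multipliers),
    the mature catalogue, the contaminant catalogue, and the background tag
    pool.  Deterministic under ``config.seed``.

    Raises ``ValueError`` if ``genome_length`` cannot host the requested
    loci without overlap.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    pool: list[str] = []          # all mature-like sequences drawn so far

    catalogue: list[tuple[str, str, str]] = []
    rows = []
    cassettes: list[dict] = []    # verified locus cassettes, in order
    n_contigs = 3

    def _assign(index: int) -> tuple[str, str]:
        return ("+" if index % 2 == 0 else "-",
                f"chr{index % n_contigs + 1}")

    # --- known miRNAs: in the catalogue, with precursor loci in the genome
    for i in range(config.n_planted_known):
        family = f"miR{1000 + i}"
        strand, contig = _assign(len(cassettes))
        mature, star, pre, cassette, m_start = _design_planted_mirna(
            rng, pool, config.backend, strand)
        pool.append(mature)
        catalogue.append((f"csn-{family}a", family, mature))
        if i % 3 == 0:  # unexpressed paralogue, 2 substitutions away
            pos = rng.choice(len(mature) - 4, 2, replace=False) + 2
            para = list(mature)
            for p in pos:
                para[p] = str(rng.choice([b for b in "ACGT" if b != para[p]]))
            catalogue.append((f"csn-{family}b", family, "".join(para)))
            pool.append("".join(para))
        rows.append(dict(mirna_id=f"csn-{family}a", family=family,
                         mature_seq=mature, star_seq=star, kind="known",
                         decoy_class="", is_known=True, precursor=pre))
        cassettes.append(dict(mirna_id=f"csn-{family}a", cassette=cassette,
                              m_start=m_start, m_len=len(mature),
                              pre_len=len(pre), strand=strand, contig=contig))

    # unexpressed extra families (catalogue noise)
    for j in range(10):
        family = f"miR{2000 + j}"
        seq = _draw_mature(rng, pool)
        pool.append(seq)
        catalogue.append((f"csn-{family}a", family, seq))

    # --- novel miRNAs: loci in the genome, absent from the catalogue
    for i in range(config.n_planted_novel):
        strand, contig = _assign(len(cassettes))
        mature, star, pre, cassette, m_start = _design_planted_mirna(
            rng, pool, config.backend, strand)
        pool.append(mature)
        rows.append(dict(mirna_id=f"novel_planted_{i + 1}", family="",
                         mature_seq=mature, star_seq=star, kind="novel",
                         decoy_class="", is_known=False, precursor=pre))
        cassettes.append(dict(mirna_id=f"novel_planted_{i + 1}",
                              cassette=cassette, m_start=m_start,
                              m_len=len(mature), pre_len=len(pre),
                              strand=strand, contig=contig))

    # --- decoys: one per class, each failing exactly one criterion
    for cls in DECOY_CLASSES[:config.n_decoy_hairpins]:
        strand, contig = _assign(len(cassettes))
        mature, pre, cassette, m_start = _design_decoy(
            rng, cls, pool, config.backend, strand)
        pool.append(mature)
        rows.append(dict(mirna_id=f"decoy_{cls}", family="",
                         mature_seq=mature, star_seq="", kind="decoy",
                         decoy_class=cls, is_known=False, precursor=pre))
        cassettes.append(dict(mirna_id=f"decoy_{cls}", cassette=cassette,
                              m_start=m_start, m_len=len(mature),
                              pre_len=len(pre), strand=strand,
                              contig=contig))

    # --- expression design
    truth = pd.DataFrame(rows)
    n_planted = len(truth)
    base = np.zeros(n_planted)
    known_mask = (truth.kind == "known").values
    novel_mask = (truth.kind == "novel").values
    lo_k, hi_k = config.known_abundance_range
    lo_n, hi_n = config.novel_abundance_range
    base[known_mask] = np.exp(rng.uniform(math.log(lo_k), math.log(hi_k),
                                          known_mask.sum()))
    base[novel_mask] = np.exp(rng.uniform(math.log(lo_n), math.log(hi_n),
                                          novel_mask.sum()))
    base[(truth.kind == "decoy").values] = 30.0
    truth["base_abundance"] = np.round(base, 1)

    for cond in config.conditions:
        truth[f"mult_{cond}"] = 1.0
    expressed = truth.kind.isin(["known", "novel"]).values
    for idx, row_i in enumerate(np.flatnonzero(expressed)):
        pattern = _EFFECT_PATTERNS[idx % len(_EFFECT_PATTERNS)]
        for cond, scale in pattern.items():
            if cond in config.conditions:
                truth.loc[truth.index[row_i], f"mult_{cond}"] = \
                    2.0 ** (scale * config.effect_log2fc)

    # --- assemble contigs from the verified cassettes
    genome: dict[str, str] = {}
    locus_rows = []
    parts: dict[str, list[str]] = {f"chr{c + 1}": [] for c in range(n_contigs)}
    offsets: dict[str, int] = {name: 0 for name in parts}
    for cas in cassettes:
        name = cas["contig"]
        off = offsets[name]
        parts[name].append(cas["cassette"])
        locus_rows.append(dict(
            mirna_id=cas["mirna_id"], contig=name,
            start=off + PAD_LEN + 1,             # precursor, 1-based
            end=off + PAD_LEN + cas["pre_len"],
            strand=cas["strand"],
            mature_start=off + cas["m_start"] + 1))
        offsets[name] += len(cas["cassette"])
    per_contig_len = config.genome_length // n_contigs
    for name in parts:
        if offsets[name] > per_contig_len:
            raise ValueError(
                f"genome_length={config.genome_length} too short to host "
                f"{len(cassettes)} planted loci without overlap "
                f"(need >= {max(offsets.values()) * n_contigs})")
        parts[name].append(_rand_seq(rng, per_contig_len - offsets[name],
                                     "AC"))
        genome[name] = "".join(parts[name])

    locus_df = pd.DataFrame(locus_rows).set_index("mirna_id")
    truth = truth.set_index("mirna_id")
    for col in ("contig", "start", "end", "strand", "mature_start"):
        truth[col] = locus_df[col]
    truth = truth.reset_index()

    # --- contaminants & background tags
    contams = _make_contaminants(rng)
    contam_seqs = [s for _, _, s in contams]
    lens = np.array(list(_BACKGROUND_LEN_PMF))
    pmf = np.array(list(_BACKGROUND_LEN_PMF.values()))
    pmf = pmf / pmf.sum()
    bg_rows = []
    n_mapped = int(config.n_background_tags * config.frac_background_mapped)
    genome_cat = " ".join(genome.values())
    contig_names = list(genome)
    planted_iv: dict[str, list[tuple[int, int]]] = {c: [] for c in genome}
    for r in locus_rows:
        planted_iv[r["contig"]].append((r["start"] - 3, r["end"] + 1))
    for b in range(config.n_background_tags):
        n = int(rng.choice(lens, p=pmf))
        if b < n_mapped:  # sampled from the unstructured genome padding
            tag = None
            for _try in range(50):
                contig = contig_names[int(rng.integers(len(contig_names)))]
                s = int(rng.integers(0, len(genome[contig]) - n))
                if any(s < hi and s + n > lo
                       for lo, hi in planted_iv[contig]):
                    continue          # never graze a planted locus
                cand = genome[contig][s:s + n]
                if set(cand) - set("AC"):
                    continue
                tag = cand
                break
            if tag is None:
                tag = _rand_seq(rng, n, "AC")
        else:
            tag = _rand_seq(rng, n)
            if tag in genome_cat or any(tag in c for c in contam_seqs) \
                    or _min_family_dist(tag, pool) < 5:
                tag = _rand_seq(rng, n)
        bg_rows.append(dict(tag=tag, weight=float(rng.lognormal(0.0, 1.2)),
                            mapped=b < n_mapped))
    background = (pd.DataFrame(bg_rows).drop_duplicates("tag")
                  .reset_index(drop=True))

    return genome, Truth(truth, catalogue, contams, background, config)


# ------------------------------------------------------------- raw libraries

def _nb_counts(rng, mean: float, dispersion: float,
               size: int | None = None) -> np.ndarray:
    if dispersion < 1e-8:
        return rng.poisson(mean, size)
    r = 1.0 / dispersion
    mean = np.asarray(mean, dtype=float)
    return rng.negative_binomial(r, r / (r + mean), size)


def simulate_libraries(truth: Truth, config: SimConfig,
                       outdir: str | Path | None = None
                       ) -> tuple[dict[str, list], pd.DataFrame]:
    """Simulate raw reads for every library.

    Returns ``(records, truth_counts)`` where ``records[library]`` is a list
    of ``(read_id_prefix, sequence, quality, count)`` groups (written as
    FASTQ when ``outdir`` is given) and ``truth_counts`` is the planted
    miRNA count table (miRNA x library).

    Planted counts are negative-binomial around base_abundance x condition
    multiplier; the ``low_support`` decoy receives a fixed total of 4 reads
    so that it always fails the read-support criterion alone.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 7_919)
    mirnas = truth.mirnas
    adapter = config.adapter_seq
    libraries = config.libraries

    frag_pool = []
    for name, cls, seq in truth.contaminants:
        for _ in range(6):
            n = int(rng.integers(20, 25))
            s = int(rng.integers(0, len(seq) - n))
            frag_pool.append(seq[s:s + n])
    lowq_pool = [_rand_seq(rng, 21) for _ in range(20)]

    junk_names = list(config.junk_fracs)
    junk_p = np.array([config.junk_fracs[k] for k in junk_names])
    counts_tbl = pd.DataFrame(0, index=mirnas.mirna_id, columns=libraries)
    records: dict[str, list] = {}

    bg = truth.background
    bg_w = bg.weight.values / bg.weight.values.sum()
    low_support_rows = mirnas.index[mirnas.decoy_class == "low_support"]

    for lib in libraries:
        cond, rep = lib.split("-")
        means = mirnas.base_abundance.values * mirnas[f"mult_{cond}"].values
        planted = _nb_counts(rng, means, config.dispersion)
        for i in low_support_rows:          # fixed total of 4 across libraries
            planted[i] = 1 if (cond != "NO" and int(rep) <= 2) else 0
        counts_tbl[lib] = planted

        n_junk = rng.multinomial(config.reads_per_library,
                                 np.append(junk_p, 1 - junk_p.sum()))
        junk = dict(zip(junk_names, n_junk[:-1]))
        n_main = int(n_junk[-1])
        n_bg = n_main - int(planted.sum())
        if n_bg < 0:
            raise ValueError("reads_per_library too small for planted abundances")
        bg_counts = rng.multinomial(n_bg, bg_w)

        recs = []
        rid = 0
        for seq, cnt in zip(mirnas.mature_seq, planted):
            if cnt > 0:
                read = seq + adapter
                recs.append((f"{lib}:p{rid}", read, "I" * len(read), int(cnt)))
            rid += 1
        for tag, cnt in zip(bg.tag.values, bg_counts):
            if cnt > 0:
                read = tag + adapter
                recs.append((f"{lib}:b{rid}", read, "I" * len(read), int(cnt)))
            rid += 1
        dimer = adapter + adapter[:10]
        recs.append((f"{lib}:dimer", dimer, "I" * len(dimer),
                     int(junk["adapter_dimer"])))
        recs.append((f"{lib}:polyA", "A" * 45, "I" * 45, int(junk["polyA"])))
        lq = rng.multinomial(junk["lowq"],
                             np.full(len(lowq_pool), 1 / len(lowq_pool)))
        for i, cnt in enumerate(lq):
            if cnt > 0:
                read = lowq_pool[i] + adapter
                recs.append((f"{lib}:lq{i}", read, "$" * len(read), int(cnt)))
        cf = rng.multinomial(junk["contaminant"],
                             np.full(len(frag_pool), 1 / len(frag_pool)))
        for i, cnt in enumerate(cf):
            if cnt > 0:
                read = frag_pool[i] + adapter
                recs.append((f"{lib}:c{i}", read, "I" * len(read), int(cnt)))
        records[lib] = recs

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        ext = ".fastq.gz" if config.gzip_fastq else ".fastq"
        for lib, recs in records.items():
            write_fastq(outdir / f"{lib}{ext}", recs)
        counts_tbl.to_csv(outdir / "truth_counts.tsv", sep="\t")
    return records, counts_tbl


# -------------------------------------------------------------- transcriptome

def default_targets_spec(truth: Truth, config: SimConfig) -> list[PlantedTarget]:
    """One to two planted target sites per effect-carrying planted miRNA."""
    scores = [0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0]
    spec: list[PlantedTarget] = []
    gi = 0
    effect_cols = [f"mult_{c}" for c in config.conditions if c != "CK"]
    for _, row in truth.mirnas.iterrows():
        if row.kind == "decoy":
            continue
        if max(abs(math.log2(row[c])) for c in effect_cols) <= 1.0:
            continue
        for k in range(2 if gi % 3 == 0 else 1):
            score = scores[(gi + k) % len(scores)]
            mode = ("translation_inhibition"
                    if score >= 1.0 and (gi + k) % 5 == 0 else "cleavage")
            spec.append(PlantedTarget(f"TEA{len(spec) + 1:06d}.1", row.mirna_id,
                                      0, score, mode))
        gi += 1
    return spec


def generate_transcriptome(truth: Truth,
                           targets_spec: list[PlantedTarget] | None,
                           config: SimConfig
                           ) -> tuple[dict[str, str], list[PlantedTarget]]:
    """Toy coding-sequence set with planted miRNA target sites.

    Each planted site is engineered so that rescoring it with the target
    module reproduces ``designed_score`` exactly and the inhibition-mode
    classifier returns ``designed_mode``; filler sequence is redrawn at
    generation time if it contains any accidental site at or below the
    score cutoff for any planted miRNA.
    """
    from . import targets as tg

    config.validate()
    rng = np.random.default_rng(config.seed + 104_729)
    if targets_spec is None:
        targets_spec = default_targets_spec(truth, config)
    cfg = tg.ScoringConfig()
    mature_by_id = dict(zip(truth.mirnas.mirna_id, truth.mirnas.mature_seq))
    all_matures = {mid: mature_by_id[mid]
                   for mid in truth.mirnas.loc[truth.mirnas.kind != "decoy",
                                               "mirna_id"]}

    by_gene: dict[str, list[PlantedTarget]] = {}
    for t in targets_spec:
        by_gene.setdefault(t.gene_id, []).append(t)
    gene_ids = list(by_gene) + [f"TEA{900_000 + i:06d}.1"
                                for i in range(config.n_genes - len(by_gene))]

    transcripts: dict[str, str] = {}
    planted: list[PlantedTarget] = []
    L = config.transcript_length
    for gene in gene_ids:
        sites = by_gene.get(gene, [])
        for attempt in range(200):
            seq = _rand_seq(rng, L)
            placed = []
            pos = 60
            for t in sites:
                site = tg.build_site(mature_by_id[t.mirna_id], t.designed_score,
                                     t.designed_mode, cfg, rng)
                seq = seq[:pos] + site + seq[pos + len(site):]
                placed.append((t, pos + 1, site))
                pos += len(site) + 80
            # reject accidental (non-designed) sites anywhere in the gene
            clean = True
            for mid, mat in all_matures.items():
                designed_pos = {p for (t, p, s) in placed if t.mirna_id == mid}
                hits = tg.ungapped_scan(mat, seq, cfg)
                if any(p not in designed_pos for p, _sc in hits):
                    clean = False
                    break
            if clean:
                break
        else:
            raise RuntimeError(f"could not build a clean transcript for {gene}")
        transcripts[gene] = seq
        for t, pos1, site in placed:
            got = tg.score_alignment(mature_by_id[t.mirna_id],
                                     seq[pos1 - 1:pos1 - 1 + len(site)], cfg)
            assert abs(got.expectation - t.designed_score) < 1e-9, \
                (gene, t, got.expectation)
            planted.append(PlantedTarget(gene, t.mirna_id, pos1,
                                         t.designed_score, t.designed_mode))
    return transcripts, planted


# ----------------------------------------------------------------- annotation

GO_TERMS = [
    ("GO:0071555", "BP", "cell wall organization"),
    ("GO:0055085", "BP", "transmembrane transport"),
    ("GO:0055114", "BP", "oxidation-reduction process"),
    ("GO:0005975", "BP", "carbohydrate metabolic process"),
    ("GO:0005886", "CC", "plasma membrane"),
    ("GO:0005618", "CC", "cell wall"),
    ("GO:0005874", "CC", "microtubule"),
    ("GO:0046872", "MF", "metal ion binding"),
    ("GO:0051015", "MF", "actin filament binding"),
    ("GO:0030599", "MF", "pectinesterase activity"),
    ("GO:0015079", "MF", "potassium ion transmembrane transporter activity"),
    ("GO:0016491", "MF", "oxidoreductase activity"),
    ("ko00500", "KEGG", "Starch and sucrose metabolism"),
    ("ko04010", "KEGG", "MAPK signaling pathway"),
    ("ko00941", "KEGG", "Flavonoid biosynthesis"),
    ("ko04144", "KEGG", "Endocytosis"),
]

ENRICHED_TERM = "GO:0071555"


def generate_annotation(gene_ids: list[str], designated: list[str],
                        config: SimConfig) -> pd.DataFrame:
    """Gene->term table with ``ENRICHED_TERM`` planted over ``designated``.

    The designated term covers 80% of the designated gene set against a 5%
    background rate; all other terms are assigned uniformly at random.
    """
    rng = np.random.default_rng(config.seed + 65_537)
    rows = []
    designated_set = set(designated)
    others = [t for t in GO_TERMS if t[0] != ENRICHED_TERM]
    info = {t[0]: t for t in GO_TERMS}
    for gene in gene_ids:
        k = int(rng.integers(2, 5))
        for i in rng.choice(len(others), k, replace=False):
            tid, ns, name = others[i]
            rows.append((gene, tid, ns, name))
        p_hit = 0.8 if gene in designated_set else 0.05
        if rng.random() < p_hit:
            tid, ns, name = info[ENRICHED_TERM]
            rows.append((gene, tid, ns, name))
    return (pd.DataFrame(rows, columns=["gene", "term", "namespace", "name"])
            .drop_duplicates().reset_index(drop=True))


# ----------------------------------------------------------------- qPCR truth

def simulate_ct_tables(truth: Truth, planted_targets: list[PlantedTarget],
                       config: SimConfig, n_assays: int = 8
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """qPCR Ct tables for a panel of planted differential miRNAs and their
    targets (references: 5.8S rRNA for miRNAs, beta-Actin for targets).

    Conditions include an LT+cPTIO rescue in which the planted LT effect is
    halved on the log2 scale.  Target-gene expression follows the inverse
    of its miRNA's fold change (one designated pair is concordant instead,
    mimicking the occasional positive miRNA-target correlation).
    """
    rng = np.random.default_rng(config.seed + 11_939)
    t_by_mirna: dict[str, str] = {}
    for t in planted_targets:
        t_by_mirna.setdefault(t.mirna_id, t.gene_id)
    effect_cols = [f"mult_{c}" for c in config.conditions if c != "CK"]
    cand = truth.mirnas[(truth.mirnas.kind != "decoy")
                        & truth.mirnas.mirna_id.isin(t_by_mirna)]
    cand = cand[(np.abs(np.log2(cand[effect_cols])) > 1).any(axis=1)]
    cand = cand.head(n_assays)

    conditions = list(config.conditions) + ["LT+cPTIO"]
    rows_m: list[tuple] = []
    rows_t: list[tuple] = []

    def emit(rows, assay, ref_name, cond, rel, ref_ct):
        for bio in range(1, 4):
            dct_noise = rng.normal(0, 0.12)
            base_ref = ref_ct + rng.normal(0, 0.1)
            for tech in range(1, 4):
                ct_ref = base_ref + rng.normal(0, 0.05)
                ct = base_ref + 5.0 - math.log2(rel) + dct_noise \
                    + rng.normal(0, 0.05)
                rows.append((assay, cond, bio, tech, round(ct, 3)))
                rows.append((ref_name, cond, bio, tech, round(ct_ref, 3)))

    for ai, (_, row) in enumerate(cand.iterrows()):
        positive_pair = ai == len(cand) - 1
        for cond in conditions:
            if cond == "LT+cPTIO":
                rel = 2.0 ** (0.5 * math.log2(row.get("mult_LT", 1.0)))
            elif cond == "CK":
                rel = 1.0
            else:
                rel = float(row[f"mult_{cond}"])
            emit(rows_m, row.mirna_id, "5.8S-rRNA", cond, rel, ref_ct=18.0)
            t_rel = rel ** (0.8 if positive_pair else -0.8)
            emit(rows_t, t_by_mirna[row.mirna_id], "beta-Actin", cond, t_rel,
                 ref_ct=20.0)

    cols = ["assay", "condition", "bio_rep", "tech_rep", "ct"]
    mdf = pd.DataFrame(rows_m, columns=cols).drop_duplicates(
        ["assay", "condition", "bio_rep", "tech_rep"]).reset_index(drop=True)
    tdf = pd.DataFrame(rows_t, columns=cols).drop_duplicates(
        ["assay", "condition", "bio_rep", "tech_rep"]).reset_index(drop=True)
    return mdf, tdf


# ------------------------------------------------------------------- exports

def write_reference_files(genome: dict[str, str], truth: Truth,
                          outdir: str | Path) -> dict[str, Path]:
    """Write genome, catalogues and truth tables; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fasta",
        "mature": outdir / "mature_catalogue.fasta",
        "contaminants": outdir / "contaminants.fasta",
        "truth": outdir / "truth_mirnas.tsv",
        "loci": outdir / "planted_loci.gff3",
    }
    write_fasta(paths["genome"], genome.items())
    write_fasta(paths["mature"],
                ((f"{mid} family={fam}", seq) for mid, fam, seq in truth.catalogue),
                rna=True)
    write_fasta(paths["contaminants"],
                ((f"{cid} class={cls}", seq) for cid, cls, seq in truth.contaminants))
    truth.mirnas.to_csv(paths["truth"], sep="\t", index=False)
    rows = []
    for _, r in truth.mirnas.iterrows():
        rows.append((r.contig, "sporomir_sim", "miRNA_primary_transcript",
                     r.start, r.end, ".", r.strand, ".",
                     {"ID": r.mirna_id, "kind": r.kind}))
    write_gff3(paths["loci"], rows)
    return paths
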