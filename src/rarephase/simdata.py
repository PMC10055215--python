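"""Synthetic populations, trios and file fixtures with known phase truth.

The generator emulates the sampling assumptions of the phasing model: for each
variant pair a population of two-locus haplotypes at configured frequencies is
drawn and paired at random into diploids (Hardy-Weinberg random mating). Trios
draw two parents the same way; each parent transmits one haplotype, optionally
recombined between the two sites and optionally hit by a recurrent mutation
(symmetric allele flip) at transmission. The coupling of every individual's
two haplotypes is recorded as phase truth, so downstream modules can be tested
against an exact gold standard.

`evolve_frequencies` provides the deterministic single-pair recombination
dynamics: the linkage-disequilibrium coefficient D decays geometrically,
D_g = D_0 (1 - r)^g, while allele frequencies are preserved, moving the
haplotype distribution toward linkage equilibrium. Drawing both the reference
panel and held-out target individuals from the evolved frequencies reproduces
the characteristic asymmetry of population-based phasing: pairs coupled in cis
lose their signal as r grows (the rare ab haplotype is eroded quickly relative
to its frequency) while pairs in trans remain decisively phased.

`write_fixtures` emits plain-text VCF 4.2 (GT:GQ:DP:AD), PED, annotation TSV,
sample-group TSV and truth TSV so the ingest pipeline can be round-tripped
byte-for-byte against the generator's internal truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .pairmodel import HAPLOTYPES, PairGenotypeCounts, _HAP_A, _HAP_B

__all__ = [
    "PairSpec",
    "SimConfig",
    "SimulatedPopulation",
    "SimulatedTrios",
    "simulate_population",
    "simulate_trios",
    "evolve_frequencies",
    "write_fixtures",
]


@dataclass
class PairSpec:
    """One simulated variant pair: positions, haplotype frequencies, annotations."""

    gene_id: str
    contig: str
    pos1: int
    pos2: int
    freqs: tuple[float, float, float, float]  # (f_AB, f_Ab, f_aB, f_ab)
    ref1: str = "A"
    alt1: str = "G"
    ref2: str = "C"
    alt2: str = "T"
    recombination_fraction: float = 0.0
    mutation_rate: float = 0.0
    consequence1: str = "missense"
    consequence2: str = "missense"
    revel1: float | None = None
    revel2: float | None = None
    methylation1: float | None = None
    methylation2: float | None = None
    context1: str | None = None
    context2: str | None = None

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        if f.shape != (4,) or np.any(f < 0) or abs(f.sum() - 1.0) > 1e-9:
            raise ValueError(f"haplotype frequencies must be a length-4 simplex, got {self.freqs}")
        if not (0.0 <= self.recombination_fraction <= 0.5):
            raise ValueError("recombination_fraction must lie in [0, 0.5]")
        if not (0.0 <= self.mutation_rate <= 1.0):
            raise ValueError("mutation_rate must lie in [0, 1]")
        if self.pos1 >= self.pos2:
            raise ValueError("pos1 must be < pos2")

    @property
    def variant_keys(self) -> tuple[str, str]:
        return (
            f"{self.contig}-{self.pos1}-{self.ref1}-{self.alt1}",
            f"{self.contig}-{self.pos2}-{self.ref2}-{self.alt2}",
        )


@dataclass
class SimConfig:
    """Study conditions for one simulation run."""

    pairs: list[PairSpec]
    n_individuals: int = 1000
    n_trios: int = 0
    seed: int = 0
    # group name -> number of population individuals; must sum to n_individuals.
    groups: dict[str, int] | None = None

    def __post_init__(self) -> None:
        if self.n_individuals < 0 or self.n_trios < 0:
            raise ValueError("sample sizes must be non-negative")
        if self.groups is not None and sum(self.groups.values()) != self.n_individuals:
            raise ValueError("group sizes must sum to n_individuals")

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        pairs = [PairSpec(**{**p, "freqs": tuple(p["freqs"])}) for p in d["pairs"]]
        return cls(pairs=pairs,
                   n_individuals=d.get("n_individuals", 1000),
                   n_trios=d.get("n_trios", 0),
                   seed=d.get("seed", 0),
                   groups=d.get("groups"))

    def to_dict(self) -> dict:
        d = asdict(self)
        for p in d["pairs"]:
            p["freqs"] = list(p["freqs"])
        return d


def evolve_frequencies(freqs, recombination_fraction: float,
                       generations: int) -> np.ndarray:
    """Deterministic decay of linkage disequilibrium under recombination.

    Allele frequencies are invariant; the disequilibrium coefficient
    ``D = f_AB f_ab - f_Ab f_aB`` decays as ``D (1-r)^g``.
    """
    f = np.asarray(freqs, dtype=float)
    pa = f[2] + f[3]  # minor allele frequency at locus A
    pb = f[1] + f[3]
    d0 = f[0] * f[3] - f[1] * f[2]
    d = d0 * (1.0 - recombination_fraction) ** generations
    eq = np.array([(1 - pa) * (1 - pb), (1 - pa) * pb, pa * (1 - pb), pa * pb])
    out = eq + d * np.array([1.0, -1.0, -1.0, 1.0])
    return np.clip(out, 0.0, 1.0)


def _phase_from_haps(h1: np.ndarray, h2: np.ndarray) -> np.ndarray:
    """Truth labels per individual: 'cis'/'trans' for double hets, '' otherwise."""
    ga = _HAP_A[h1] + _HAP_A[h2]
    gb = _HAP_B[h1] + _HAP_B[h2]
    double_het = (ga == 1) & (gb == 1)
    # among double hets: haplotype multiset {AB, ab} -> cis, {Ab, aB} -> trans
    cis = double_het & (((h1 == 0) & (h2 == 3)) | ((h1 == 3) & (h2 == 0)))
    trans = double_het & (((h1 == 1) & (h2 == 2)) | ((h1 == 2) & (h2 == 1)))
    out = np.full(h1.shape, "", dtype=object)
    out[cis] = "cis"
    out[trans] = "trans"
    return out


class SimulatedPopulation:
    """Diploid population with per-pair haplotype truth.

    ``hap1``/``hap2`` are (n_individuals, n_pairs) arrays of haplotype indices
    in :data:`HAPLOTYPES` order; genotype dosages derive from them.
    """

    def __init__(self, config: SimConfig, hap1: np.ndarray, hap2: np.ndarray,
                 sample_ids: list[str], group_of: dict[str, str]) -> None:
        self.config = config
        self.hap1 = hap1
        self.hap2 = hap2
        self.sample_ids = sample_ids
        self.group_of = group_of  # sample id -> group name

    @property
    def n_individuals(self) -> int:
        return self.hap1.shape[0]

    def dosages(self, pair_index: int) -> tuple[np.ndarray, np.ndarray]:
        """Minor-allele dosage at each site of one pair, per individual."""
        h1 = self.hap1[:, pair_index]
        h2 = self.hap2[:, pair_index]
        return _HAP_A[h1] + _HAP_A[h2], _HAP_B[h1] + _HAP_B[h2]

    def truth_phase(self, pair_index: int) -> np.ndarray:
        return _phase_from_haps(self.hap1[:, pair_index], self.hap2[:, pair_index])

    def truth_pair_counts(self, pair_index: int,
                          sample_mask: np.ndarray | None = None) -> PairGenotypeCounts:
        """Direct tabulation of the 3x3 genotype table from the truth haplotypes."""
        ga, gb = self.dosages(pair_index)
        if sample_mask is not None:
            ga, gb = ga[sample_mask], gb[sample_mask]
        table = np.bincount(ga * 3 + gb, minlength=9).reshape(3, 3)
        return PairGenotypeCounts(table)


class SimulatedTrios:
    """Trios with transmitted-haplotype truth.

    Arrays are (n_trios, n_pairs): ``mother_hap1/2``, ``father_hap1/2`` for the
    parents and ``child_hap_m``/``child_hap_p`` for the haplotypes the child
    received from mother and father (after any recombination/mutation).
    """

    def __init__(self, config: SimConfig, mother_hap1, mother_hap2,
                 father_hap1, father_hap2, child_hap_m, child_hap_p,
                 trio_ids: list[tuple[str, str, str]]) -> None:
        self.config = config
        self.mother_hap1 = mother_hap1
        self.mother_hap2 = mother_hap2
        self.father_hap1 = father_hap1
        self.father_hap2 = father_hap2
        self.child_hap_m = child_hap_m
        self.child_hap_p = child_hap_p
        #: list of (child_id, mother_id, father_id)
        self.trio_ids = trio_ids

    @property
    def n_trios(self) -> int:
        return self.child_hap_m.shape[0]

    def child_dosages(self, pair_index: int) -> tuple[np.ndarray, np.ndarray]:
        hm = self.child_hap_m[:, pair_index]
        hp = self.child_hap_p[:, pair_index]
        return _HAP_A[hm] + _HAP_A[hp], _HAP_B[hm] + _HAP_B[hp]

    def child_truth_phase(self, pair_index: int) -> np.ndarray:
        return _phase_from_haps(self.child_hap_m[:, pair_index],
                                self.child_hap_p[:, pair_index])

    def member_dosages(self, member: str, pair_index: int) -> tuple[np.ndarray, np.ndarray]:
        if member == "child":
            return self.child_dosages(pair_index)
        h1 = getattr(self, f"{member}_hap1")[:, pair_index]
        h2 = getattr(self, f"{member}_hap2")[:, pair_index]
        return _HAP_A[h1] + _HAP_A[h2], _HAP_B[h1] + _HAP_B[h2]


def _draw_haps(rng: np.random.Generator, freqs, size) -> np.ndarray:
    return rng.choice(4, size=size, p=np.asarray(freqs, dtype=float))


def simulate_population(config: SimConfig,
                        rng: np.random.Generator | None = None) -> SimulatedPopulation:
    """Draw 2n haplotypes per pair from the configured frequencies, pair at random."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n, k = config.n_individuals, len(config.pairs)
    hap1 = np.zeros((n, k), dtype=np.int8)
    hap2 = np.zeros((n, k), dtype=np.int8)
    for j, pair in enumerate(config.pairs):
        hap1[:, j] = _draw_haps(rng, pair.freqs, n)
        hap2[:, j] = _draw_haps(rng, pair.freqs, n)
    sample_ids = [f"S{i:06d}" for i in range(n)]
    group_of: dict[str, str] = {}
    if config.groups:
        start = 0
        for gname, gsize in config.groups.items():
            for sid in sample_ids[start:start + gsize]:
                group_of[sid] = gname
            start += gsize
    else:
        group_of = {sid: "all" for sid in sample_ids}
    return SimulatedPopulation(config, hap1, hap2, sample_ids, group_of)


def _transmit(rng: np.random.Generator, h1: np.ndarray, h2: np.ndarray,
              recomb: float, mut: float) -> np.ndarray:
    """Transmitted haplotype per parent: pick one, recombine, mutate."""
    n = h1.shape[0]
    pick = rng.random(n) < 0.5
    chosen = np.where(pick, h1, h2)
    other = np.where(pick, h2, h1)
    a = _HAP_A[chosen].copy()
    b = _HAP_B[chosen].copy()
    if recomb > 0:
        swap = rng.random(n) < recomb
        b[swap] = _HAP_B[other][swap]  # crossover between the two sites
    if mut > 0:
        a ^= (rng.random(n) < mut).astype(a.dtype)
        b ^= (rng.random(n) < mut).astype(b.dtype)
    return (2 * a + b).astype(np.int8)


def simulate_trios(config: SimConfig,
                   rng: np.random.Generator | None = None) -> SimulatedTrios:
    """Draw parents under HWE; transmit one (possibly recombined/mutated) haplotype each."""
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    n, k = config.n_trios, len(config.pairs)
    shape = (n, k)
    m1 = np.zeros(shape, dtype=np.int8)
    m2 = np.zeros(shape, dtype=np.int8)
    f1 = np.zeros(shape, dtype=np.int8)
    f2 = np.zeros(shape, dtype=np.int8)
    cm = np.zeros(shape, dtype=np.int8)
    cp = np.zeros(shape, dtype=np.int8)
    for j, pair in enumerate(config.pairs):
        m1[:, j] = _draw_haps(rng, pair.freqs, n)
        m2[:, j] = _draw_haps(rng, pair.freqs, n)
        f1[:, j] = _draw_haps(rng, pair.freqs, n)
        f2[:, j] = _draw_haps(rng, pair.freqs, n)
        cm[:, j] = _transmit(rng, m1[:, j], m2[:, j],
                             pair.recombination_fraction, pair.mutation_rate)
        cp[:, j] = _transmit(rng, f1[:, j], f2[:, j],
                             pair.recombination_fraction, pair.mutation_rate)
    trio_ids = [(f"T{i:05d}c", f"T{i:05d}m", f"T{i:05d}f") for i in range(n)]
    return SimulatedTrios(config, m1, m2, f1, f2, cm, cp, trio_ids)


# ---------------------------------------------------------------------------
# Fixture writing

_VCF_HEADER = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
"""

_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def _default_format(dosage: int, depth: int = 30) -> tuple[int, int, tuple[int, int]]:
    """(GQ, DP, AD) passing the default QC for a given dosage."""
    if dosage == 1:
        return 99, depth, (depth // 2, depth - depth // 2)
    if dosage == 2:
        return 99, depth, (0, depth)
    return 99, depth, (depth, 0)


def write_fixtures(population: SimulatedPopulation,
                   trios: SimulatedTrios | None,
                   outdir: str | Path,
                   qc_overrides: dict[tuple[str, str], dict] | None = None) -> dict[str, Path]:
    """Write VCF/PED/annotation/group/truth text fixtures for a simulation.

    ``qc_overrides`` plants specific FORMAT values keyed by
    ``(sample_id, variant_key)``, e.g. ``{"gq": 19}`` to create a genotype the
    QC filter must remove. Returns a dict of written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = population.config
    qc_overrides = qc_overrides or {}

    # Site-major layout: two sites per pair, sorted by (contig, position).
    sites = []  # (contig, pos, ref, alt, pair_index, site_index)
    for j, pair in enumerate(config.pairs):
        sites.append((pair.contig, pair.pos1, pair.ref1, pair.alt1, j, 0))
        sites.append((pair.contig, pair.pos2, pair.ref2, pair.alt2, j, 1))
    sites.sort(key=lambda s: (s[0], s[1], s[2], s[3]))
    keys = [f"{c}-{p}-{r}-{a}" for c, p, r, a, _, _ in sites]
    if len(set(keys)) != len(keys):
        raise ValueError("simulated sites collide; choose distinct positions")

    samples: list[str] = list(population.sample_ids)
    dosage_cols: dict[str, np.ndarray] = {}
    n_sites = len(sites)
    pop_dos = np.zeros((population.n_individuals, n_sites), dtype=np.int8)
    for s_idx, (_, _, _, _, j, site) in enumerate(sites):
        ga, gb = population.dosages(j)
        pop_dos[:, s_idx] = ga if site == 0 else gb
    matrices = [pop_dos]
    if trios is not None and trios.n_trios:
        trio_dos = np.zeros((3 * trios.n_trios, n_sites), dtype=np.int8)
        for s_idx, (_, _, _, _, j, site) in enumerate(sites):
            for m_idx, member in enumerate(("child", "mother", "father")):
                ga, gb = trios.member_dosages(member, j)
                trio_dos[m_idx::3, s_idx] = ga if site == 0 else gb
        for cid, mid, fid in trios.trio_ids:
            samples.extend([cid, mid, fid])
        matrices.append(trio_dos)
    dosages = np.vstack(matrices)

    # --- VCF -------------------------------------------------------------
    vcf_path = outdir / "cohort.vcf"
    with open(vcf_path, "w") as fh:
        fh.write(_VCF_HEADER)
        for contig in sorted({s[0] for s in sites}):
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for s_idx, (contig, pos, ref, alt, j, site) in enumerate(sites):
            key = keys[s_idx]
            fields = [contig, str(pos), key, ref, alt, ".", "PASS", ".",
                      "GT:GQ:DP:AD"]
            col = dosages[:, s_idx]
            for samp, dos in zip(samples, col):
                gq, dp, (ad_r, ad_a) = _default_format(int(dos))
                override = qc_overrides.get((samp, key))
                if override:
                    gq = override.get("gq", gq)
                    dp = override.get("dp", dp)
                    ad_r, ad_a = override.get("ad", (ad_r, ad_a))
                fields.append(f"{_GT_STR[int(dos)]}:{gq}:{dp}:{ad_r},{ad_a}")
            fh.write("\t".join(fields) + "\n")

    # --- annotation TSV --------------------------------------------------
    group_names = sorted(set(population.group_of.values()))
    ann_path = outdir / "annotation.tsv"
    pop_ids = np.asarray(population.sample_ids)
    group_masks = {g: np.array([population.group_of[s] == g for s in population.sample_ids])
                   for g in group_names}
    with open(ann_path, "w") as fh:
        cols = ["chrom", "pos", "ref", "alt", "gene_id", "consequence_class",
                "revel", "methylation", "context", "AC_global", "AN_global"]
        for g in group_names:
            cols += [f"AC_{g}", f"AN_{g}"]
        fh.write("\t".join(cols) + "\n")
        for s_idx, (contig, pos, ref, alt, j, site) in enumerate(sites):
            pair = config.pairs[j]
            cons = pair.consequence1 if site == 0 else pair.consequence2
            revel = pair.revel1 if site == 0 else pair.revel2
            meth = pair.methylation1 if site == 0 else pair.methylation2
            ctx = pair.context1 if site == 0 else pair.context2
            col = pop_dos[:, s_idx]
            ac = int(col.sum())
            an = 2 * len(col)
            row = [contig, str(pos), ref, alt, pair.gene_id, cons,
                   "" if revel is None else f"{revel}",
                   "" if meth is None else f"{meth}",
                   "" if ctx is None else ctx, str(ac), str(an)]
            for g in group_names:
                sub = col[group_masks[g]]
                row += [str(int(sub.sum())), str(2 * len(sub))]
            fh.write("\t".join(row) + "\n")

    # --- sample groups ----------------------------------------------------
    groups_path = outdir / "groups.tsv"
    with open(groups_path, "w") as fh:
        fh.write("sample_id\tgroup\n")
        for sid in population.sample_ids:
            fh.write(f"{sid}\t{population.group_of[sid]}\n")
        if trios is not None:
            for cid, mid, fid in trios.trio_ids:
                for sid in (cid, mid, fid):
                    fh.write(f"{sid}\ttrio\n")

    # --- pedigree ---------------------------------------------------------
    ped_path = outdir / "trios.ped"
    with open(ped_path, "w") as fh:
        if trios is not None:
            for i, (cid, mid, fid) in enumerate(trios.trio_ids):
                fh.write(f"FAM{i:05d}\t{cid}\t{fid}\t{mid}\t0\t0\n")
                fh.write(f"FAM{i:05d}\t{fid}\t0\t0\t1\t0\n")
                fh.write(f"FAM{i:05d}\t{mid}\t0\t0\t2\t0\n")

    # --- truth ------------------------------------------------------------
    truth_path = outdir / "truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write("individual\tgene_id\tvariant1\tvariant2\ttruth_label\tcohort\n")
        for j, pair in enumerate(config.pairs):
            k1, k2 = pair.variant_keys
            labels = population.truth_phase(j)
            for sid, lab in zip(population.sample_ids, labels):
                if lab:
                    fh.write(f"{sid}\t{pair.gene_id}\t{k1}\t{k2}\t{lab}\tpopulation\n")
            if trios is not None and trios.n_trios:
                labels = trios.child_truth_phase(j)
                for (cid, _, _), lab in zip(trios.trio_ids, labels):
                    if lab:
                        fh.write(f"{cid}\t{pair.gene_id}\t{k1}\t{k2}\t{lab}\ttrio\n")

    config_path = outdir / "config.json"
    config_path.write_text(json.dumps(config.to_dict(), indent=2))
    return {"vcf": vcf_path, "annotation": ann_path, "groups": groups_path,
            "ped": ped_path, "truth": truth_path, "config": config_path}
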