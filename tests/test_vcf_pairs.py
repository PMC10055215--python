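"""VCF ingest, genotype QC, rare-variant filtering, pair counting."""

import numpy as np
import pandas as pd
import pytest

from rarephase.pairmodel import PairGenotypeCounts
from rarephase.simdata import PairSpec, SimConfig, simulate_population, \
    simulate_trios, write_fixtures
from rarephase.vcf_pairs import (BiallelicVariant, VariantPair,
                                 apply_genotype_qc, build_pair_table,
                                 count_pair_genotypes, enumerate_pairs,
                                 filter_variants, flag_singleton_singleton,
                                 load_variants)


def make_variant(**kw):
    defaults = dict(contig="1", position=100, ref="A", alt="G", gene_id="G1",
                    consequence_class="missense",
                    af_by_group={"global": (10, 10000)})
    defaults.update(kw)
    return BiallelicVariant(**defaults)


@pytest.fixture(scope="module")
def sim_fixture(tmp_path_factory):
    cfg = SimConfig(
        pairs=[
            PairSpec("G1", "1", 1000, 2000, (0.9, 0.05, 0.04, 0.01)),
            PairSpec("G2", "2", 500, 900, (0.98, 0.01, 0.01, 0.0)),
            PairSpec("G3", "3", 100, 400, (0.97, 0.0, 0.01, 0.02)),
        ],
        n_individuals=300, n_trios=8, seed=12,
        groups={"nfe": 200, "afr": 100},
    )
    pop = simulate_population(cfg)
    trios = simulate_trios(cfg)
    outdir = tmp_path_factory.mktemp("fixture")
    paths = write_fixtures(pop, trios, outdir)
    return cfg, pop, trios, paths


class TestLoadVariants:
    def test_genotype_dosages_and_missing(self, tmp_path):
        vcf = tmp_path / "t.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\n"
            "1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"
            "1\t200\t.\tC\tT\t.\tPASS\t.\tGT\t./.\t0/0\t0/1\n"
        )
        ds = load_variants(vcf)
        np.testing.assert_array_equal(ds.genotypes[:, 0], [0, 1, 2])
        np.testing.assert_array_equal(ds.genotypes[:, 1], [-1, 0, 1])
        assert not ds.variants[0].annotated

    def test_multiallelic_record_is_hard_error(self, tmp_path):
        vcf = tmp_path / "t.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            "1\t100\t.\tA\tG,T\t.\tPASS\t.\tGT\t0/1\n"
        )
        with pytest.raises(ValueError, match="multiallelic"):
            load_variants(vcf)

    def test_annotation_joined(self, sim_fixture):
        _, _, _, paths = sim_fixture
        ds = load_variants(paths["vcf"], paths["annotation"], paths["groups"])
        v = ds.variants[0]
        assert v.gene_id and v.annotated
        assert "global" in v.af_by_group

    def test_annotation_key_collision_rejected(self, tmp_path, sim_fixture):
        _, _, _, paths = sim_fixture
        ann = pd.read_csv(paths["annotation"], sep="\t")
        dup = pd.concat([ann, ann.iloc[[0]]])
        p = tmp_path / "dup.tsv"
        dup.to_csv(p, sep="\t", index=False)
        with pytest.raises(ValueError, match="collision"):
            load_variants(paths["vcf"], p)


class TestGenotypeQC:
    def _dataset(self, tmp_path, fmt_rows):
        vcf = tmp_path / "qc.vcf"
        samples = [f"S{i}" for i in range(len(fmt_rows))]
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="q">\n'
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="d">\n'
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="a">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples) + "\n"
            + "1\t100\t.\tA\tG\t.\tPASS\t.\tGT:GQ:DP:AD\t"
            + "\t".join(fmt_rows) + "\n"
        )
        return load_variants(vcf)

    def test_thresholds_are_strict_inequalities(self, tmp_path):
        ds = self._dataset(tmp_path, [
            "0/1:21:11:8,3",    # AB = 3/11 ~ 0.27 -> kept
            "0/1:20:30:15,15",  # GQ == 20 -> removed (strict >)
            "0/1:99:10:5,5",    # DP == 10 -> removed
            "0/1:99:30:24,6",   # AB = 0.2 exactly -> removed
            "0/0:19:30:30,0",   # hom-ref GQ 19 -> removed
            "1/1:99:30:0,30",   # hom-alt, no AB requirement -> kept
        ])
        qc = apply_genotype_qc(ds)
        np.testing.assert_array_equal(qc.genotypes[:, 0], [1, -1, -1, -1, -1, 2])

    def test_qc_never_unmasks_genotypes(self, sim_fixture):
        _, _, _, paths = sim_fixture
        ds = load_variants(paths["vcf"], paths["annotation"], paths["groups"])
        qc = apply_genotype_qc(ds)
        assert np.all((qc.genotypes == ds.genotypes) | (qc.genotypes == -1))

    def test_missing_format_fields_warn_or_error(self, tmp_path):
        vcf = tmp_path / "nofmt.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            "1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\n"
        )
        ds = load_variants(vcf)
        with pytest.warns(UserWarning, match="skipped"):
            apply_genotype_qc(ds)
        with pytest.raises(ValueError, match="FORMAT"):
            apply_genotype_qc(ds, on_missing_format="error")


class TestFilterVariants:
    def test_af_cap_is_strict(self):
        at_cap = make_variant(af_by_group={"global": (500, 10000)})  # AF 5%
        below = make_variant(position=101, af_by_group={"global": (499, 10000)})
        kept = filter_variants([at_cap, below])
        assert kept == [below]

    def test_consequence_classes(self):
        syn = make_variant(consequence_class="synonymous")
        other = make_variant(position=101, consequence_class="other")
        deep_intronic = make_variant(position=102, consequence_class="intronic")
        assert filter_variants([syn, other, deep_intronic]) == [syn]

    def test_population_specific_mode(self):
        v = make_variant(af_by_group={"global": (10, 10000), "fin": (600, 10000)})
        assert filter_variants([v]) == [v]
        assert filter_variants([v], population="fin") == []

    def test_sex_chromosomes_excluded_on_flag(self):
        x = make_variant(contig="chrX")
        assert filter_variants([x]) == [x]
        assert filter_variants([x], exclude_sex_chromosomes=True) == []


class TestEnumeratePairs:
    def test_pair_count_is_combinatorial(self):
        vs = [make_variant(position=100 + i) for i in range(4)]
        assert len(enumerate_pairs(vs)) == 6
        assert enumerate_pairs(vs[:1]) == []

    def test_overlapping_genes_pair_within_each_gene_only(self):
        # shared variant sits in both genes; brute-force enumeration of the
        # 5-variant toy annotation gives C(3,2) + C(3,2) = 6 within-gene pairs
        g1 = [make_variant(position=p, gene_id="A") for p in (100, 200)]
        g2 = [make_variant(position=p, gene_id="B") for p in (400, 500)]
        shared_a = make_variant(position=300, gene_id="A")
        shared_b = make_variant(position=300, gene_id="B")
        pairs = enumerate_pairs(g1 + g2 + [shared_a, shared_b])
        assert len(pairs) == 6
        assert all(p.v1.gene_id == p.v2.gene_id for p in pairs)
        keys = {(p.gene_id, p.v1.position, p.v2.position) for p in pairs}
        expected = {("A", 100, 200), ("A", 100, 300), ("A", 200, 300),
                    ("B", 300, 400), ("B", 300, 500), ("B", 400, 500)}
        assert keys == expected

    def test_canonical_order_enforced(self):
        v1 = make_variant(position=100)
        v2 = make_variant(position=200)
        with pytest.raises(ValueError, match="canonically"):
            VariantPair(v2, v1)


class TestCountPairGenotypes:
    def _toy_dataset(self, genotypes):
        from rarephase.vcf_pairs import VariantDataset
        v1 = make_variant(position=100)
        v2 = make_variant(position=200, ref="C", alt="T")
        samples = [f"S{i}" for i in range(len(genotypes))]
        return VariantDataset([v1, v2], np.array(genotypes, dtype=np.int16),
                              samples, {s: "all" for s in samples}), \
            VariantPair(v1, v2)

    def test_direct_tabulation(self):
        ds, pair = self._toy_dataset([[0, 0], [1, 0], [0, 1], [1, 1], [2, 2]])
        counts = count_pair_genotypes(pair, ds)
        assert counts.n_total == 5
        assert counts.table[0, 0] == 1 and counts.table[1, 0] == 1
        assert counts.table[0, 1] == 1 and counts.table[1, 1] == 1
        assert counts.table[2, 2] == 1

    def test_missing_genotype_excludes_individual(self):
        ds, pair = self._toy_dataset([[0, 0], [1, -1]])
        counts = count_pair_genotypes(pair, ds)
        assert counts.n_total == 1
        assert counts.table.sum() == 1

    def test_group_additivity(self, sim_fixture):
        cfg, pop, trios, paths = sim_fixture
        ds = load_variants(paths["vcf"], paths["annotation"], paths["groups"])
        pairs = enumerate_pairs(ds.variants)
        for pair in pairs:
            per_group = sum(count_pair_genotypes(pair, ds, g).table
                            for g in ("nfe", "afr", "trio"))
            cosmo = count_pair_genotypes(pair, ds).table
            np.testing.assert_array_equal(per_group, cosmo)

    def test_round_trip_equals_simulator_truth(self, sim_fixture):
        cfg, pop, trios, paths = sim_fixture
        ds = load_variants(paths["vcf"], paths["annotation"], paths["groups"])
        pairs = enumerate_pairs(ds.variants)
        pop_groups = ("nfe", "afr")
        for j, spec in enumerate(cfg.pairs):
            k1, k2 = spec.variant_keys
            pair = next(p for p in pairs if {p.v1.key, p.v2.key} == {k1, k2})
            got = sum(count_pair_genotypes(pair, ds, g).table for g in pop_groups)
            want = pop.truth_pair_counts(j).table
            if pair.v1.key != k1:
                want = want.T
            np.testing.assert_array_equal(got, want)

    def test_qc_monotonically_reduces_counts(self, sim_fixture):
        cfg, pop, trios, paths = sim_fixture
        import rarephase.simdata as sd
        overrides = {("S000000", cfg.pairs[0].variant_keys[0]): {"gq": 19},
                     ("S000001", cfg.pairs[0].variant_keys[1]): {"dp": 5}}
        outdir = paths["vcf"].parent / "qcfail"
        paths2 = sd.write_fixtures(pop, trios, outdir, qc_overrides=overrides)
        ds = load_variants(paths2["vcf"], paths2["annotation"], paths2["groups"])
        qc = apply_genotype_qc(ds)
        pairs = enumerate_pairs(ds.variants)
        for pair in pairs:
            before = count_pair_genotypes(pair, ds).table
            after = count_pair_genotypes(pair, qc).table
            assert after.sum() <= before.sum()
            # per-cell counts can only lose the two planted individuals
            assert (before.sum() - after.sum()) <= 2


class TestSingletonSingleton:
    @pytest.mark.parametrize("cells,expected", [
        ({"AABB": 99, "AaBb": 1}, True),
        ({"AABB": 98, "AaBB": 1, "AABb": 1}, False),
        ({"AABB": 98, "AaBb": 2}, False),
    ])
    def test_flag(self, cells, expected):
        counts = PairGenotypeCounts.from_dict(cells)
        assert flag_singleton_singleton(counts) is expected


class TestBuildPairTable:
    def test_table_contents_and_cocarrier_filter(self, sim_fixture):
        cfg, pop, trios, paths = sim_fixture
        ds = load_variants(paths["vcf"], paths["annotation"], paths["groups"])
        table = build_pair_table(ds)
        assert set(table["label"]) <= {"cis", "trans", "indeterminate",
                                       "no_prediction"}
        # every emitted pair has at least one joint carrier
        joint = (table[["n_AaBb", "n_aaBb", "n_Aabb", "n_aabb"]].sum(axis=1)
                 + table["n_aaBB"] * 0)
        carrier_cells = table[["n_AaBb", "n_aaBb", "n_Aabb", "n_aabb"]].sum(axis=1)
        assert (carrier_cells > 0).all()
        all_pairs = build_pair_table(ds, require_cocarrier=False)
        assert len(all_pairs) >= len(table)
        # frequencies sum to one per row
        freq_cols = [c for c in table.columns if c.startswith("freq_")]
        np.testing.assert_allclose(table[freq_cols].sum(axis=1), 1.0, atol=1e-9)
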