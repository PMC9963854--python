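"""Generator correctness: gene layout, SNP planting, read and count simulation."""

import numpy as np
import pytest
from scipy import stats as sps

from biallelic.io import write_sam
from biallelic.pileup import call_variants, pileup
from biallelic.scoring import filter_biallelic_snps
from biallelic.simulate import (
    DEGSimConfig,
    SimConfig,
    make_gene_models,
    make_sample_meta,
    plant_parental_snps,
    simulate_allelic_dataset,
    simulate_counts_and_degs,
    simulate_het_site_pileups,
    simulate_reads,
)
from biallelic.types import GeneModel

from conftest import make_gene


class TestGeneModels:
    def test_study_scale_layout(self):
        """Ten imprinted + 73 neighbour genes over six loci on four chromosomes."""
        models = make_gene_models(SimConfig(seed=7))
        assert len(models) == 83
        assert sum(m.imprinted for m in models) == 10
        assert len({m.locus_id for m in models}) == 6
        assert len({m.chromosome for m in models}) == 4
        for locus in {m.locus_id for m in models}:
            members = [m for m in models if m.locus_id == locus]
            assert any(m.imprinted for m in members)
            assert any(not m.imprinted for m in members)

    def test_degenerate_single_neighbour(self):
        models = make_gene_models(
            SimConfig(n_imprinted_genes=0, n_neighbour_genes=1, seed=1)
        )
        assert len(models) == 1
        assert not models[0].imprinted

    def test_deterministic_under_seed(self):
        cfg = SimConfig(seed=42)
        assert make_gene_models(cfg) == make_gene_models(cfg)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_samples_per_group": 0},
            {"n_imprinted_genes": 0, "n_neighbour_genes": 0},
            {"transcript_len_range": (0, 100)},
            {"allelic_ratio_biallelic": 1.5},
            {"base_error_rate": 0.5},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs)


class TestPlantSnps:
    def test_zero_density_gives_identical_haplotypes(self):
        gene = make_gene(length=5000)
        hap = plant_parental_snps(gene, 0.0, 11)
        assert hap.maternal == hap.paternal
        assert hap.het_positions == ()

    def test_haplotypes_differ_exactly_at_planted_positions(self):
        gene = make_gene(length=4000)
        hap = plant_parental_snps(gene, 2.0, 5)
        diffs = tuple(
            i for i, (a, b) in enumerate(zip(hap.maternal, hap.paternal)) if a != b
        )
        assert diffs == hap.het_positions
        assert all(0 <= p < 4000 for p in hap.het_positions)

    def test_planted_count_follows_poisson(self):
        """Total sites over 200 seeds inside the Poisson(200 * 10) 99% interval."""
        gene = make_gene(length=10000)
        total = sum(
            len(plant_parental_snps(gene, 1.0, seed).het_positions)
            for seed in range(200)
        )
        lo, hi = sps.poisson.interval(0.99, 200 * 10.0)
        assert lo <= total <= hi


class TestSimulateReads:
    def small_config(self, **kwargs):
        defaults = dict(
            transcript_len_range=(300, 300),
            mean_coverage=200.0,
            read_len=100,
            base_error_rate=0.0,
            seed=0,
        )
        defaults.update(kwargs)
        return SimConfig(**defaults)

    def test_read_longer_than_transcript_rejected(self):
        gene = make_gene(length=50)
        hap = plant_parental_snps(gene, 0.0, 1)
        with pytest.raises(ValueError, match="read length"):
            simulate_reads(hap, 0.5, self.small_config(), 1)

    def test_total_nucleotides_match_target_coverage(self):
        gene = make_gene(length=300)
        hap = plant_parental_snps(gene, 1.0, 3)
        reads = simulate_reads(hap, 0.5, self.small_config(), 3)
        total_nt = sum(len(r.query_sequence) for r in reads)
        assert abs(total_nt - 200.0 * 300) <= 0.1 * 200.0 * 300

    def test_monoallelic_reads_show_no_intermediate_frequency(self):
        """allelic_ratio 1, no error: every het site reads at 100%, none in 20-80%."""
        gene = make_gene(length=300, chromosome="t", start=0)
        cfg = self.small_config()
        hap = plant_parental_snps(gene, 3.0, 5)
        assert hap.het_positions
        reads = simulate_reads(hap, 1.0, cfg, 5, reference_name="t")
        sites = pileup(reads, gene, {"t": hap.paternal})
        calls = call_variants(sites)
        assert {c.position - 1 for c in calls} >= set(hap.het_positions)
        assert filter_biallelic_snps(calls) == []

    def test_heterozygous_site_frequency_binomial(self):
        """Bi-allelic 50/50 coverage-200 site reads 40-60% VF in >=95/100 seeds."""
        cfg = self.small_config()
        hits = trials = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            gene = make_gene(length=300, chromosome="t")
            hap = plant_parental_snps(gene, 0.0, rng)
            pos = 150
            maternal = hap.maternal[:pos] + ("A" if hap.maternal[pos] != "A" else "C") \
                + hap.maternal[pos + 1 :]
            hap = type(hap)(maternal=maternal, paternal=hap.paternal, het_positions=(pos,))
            reads = simulate_reads(hap, 0.5, cfg, rng, reference_name="t")
            window = GeneModel(gene_id="w", chromosome="t", start=pos, end=pos + 1)
            sites = pileup(reads, window, {"t": hap.paternal})
            (site,) = sites
            alt = site.base_counts.get(maternal[pos], 0)
            vf = 100.0 * alt / site.depth
            trials += 1
            hits += 40.0 <= vf <= 60.0
        assert trials == 100
        assert hits >= 95

    def test_allele_counts_are_binomial(self):
        """Chi-square GOF of maternal counts at a planted site over 200 replicates."""
        cfg = self.small_config(base_error_rate=0.005)
        pos = 150
        chi2 = 0.0
        n_rep = 200
        p = 0.5 * (1 - 0.005) + 0.5 * 0.005 / 3
        for seed in range(n_rep):
            rng = np.random.default_rng(10_000 + seed)
            gene = make_gene(length=300, chromosome="t")
            hap = plant_parental_snps(gene, 0.0, rng)
            alt_base = "A" if hap.maternal[pos] != "A" else "C"
            maternal = hap.maternal[:pos] + alt_base + hap.maternal[pos + 1 :]
            hap = type(hap)(maternal=maternal, paternal=hap.paternal, het_positions=(pos,))
            reads = simulate_reads(hap, 0.5, cfg, rng, reference_name="t")
            window = GeneModel(gene_id="w", chromosome="t", start=pos, end=pos + 1)
            (site,) = pileup(reads, window, {"t": hap.paternal})
            d = site.depth
            m = site.base_counts.get(alt_base, 0)
            chi2 += (m - d * p) ** 2 / (d * p * (1 - p))
        assert sps.chi2.sf(chi2, df=n_rep) > 0.01

    def test_identical_seed_gives_identical_sam_bytes(self, tmp_path):
        cfg = self.small_config(base_error_rate=0.01)
        gene = make_gene(length=300)
        out = []
        for run in range(2):
            hap = plant_parental_snps(gene, 1.0, 99)
            reads = simulate_reads(hap, 0.5, cfg, 99)
            path = tmp_path / f"run{run}.sam"
            write_sam(path, {"ref": 300}, reads)
            out.append(path.read_bytes())
        assert out[0] == out[1]


class TestSitePileupShortcut:
    def test_monoallelic_limit_yields_no_biallelic_evidence(self, rng):
        cfg = SimConfig(base_error_rate=0.0, seed=0)
        gene = make_gene(length=2000)
        sites = simulate_het_site_pileups(gene, 5, 1.0, cfg, rng)
        calls = call_variants(sites)
        assert all(c.variant_frequency > 95 for c in calls)
        assert filter_biallelic_snps(calls) == []

    def test_alt_fraction_matches_read_level_model(self, rng):
        """Site-level shortcut and read-level route share the same Binomial mean."""
        cfg = SimConfig(base_error_rate=0.005, seed=0)
        gene = make_gene(length=2000)
        p_expected = 0.5 * (1 - 0.005) + 0.5 * 0.005 / 3
        alt = depth = 0
        for _ in range(50):
            for s in simulate_het_site_pileups(gene, 4, 0.5, cfg, rng):
                d = s.depth
                a = d - s.base_counts.get(s.ref_base, 0)
                alt += a
                depth += d
        assert sps.binomtest(alt, depth, p_expected).pvalue > 0.01


class TestSampleDesign:
    def test_two_balanced_groups_with_covariate_levels(self):
        meta = make_sample_meta(SimConfig(seed=0))
        assert len(meta) == 10
        groups = [m.group for m in meta]
        assert groups.count("MT-") == groups.count("MT+") == 5
        for field in ("sex", "sampling_date", "library_date"):
            per_group = {
                g: {getattr(m, field) for m in meta if m.group == g}
                for g in ("MT-", "MT+")
            }
            assert all(len(v) == 2 for v in per_group.values()), field

    def test_dataset_truth_never_feeds_scoring(self):
        """Summaries are computed before truth is attached; columns don't leak."""
        ds = simulate_allelic_dataset(
            SimConfig(n_imprinted_genes=2, n_neighbour_genes=2, seed=5)
        )
        assert {"true_allelic_ratio", "mono_allelic"} <= set(ds.truth.columns)
        for s in ds.summaries:
            assert not hasattr(s, "true_allelic_ratio")


class TestCountsAndDegs:
    def test_null_study_controls_false_discoveries(self):
        """With no planted effects, mean discoveries at FDR<0.1 stay below 10%."""
        fp = []
        for seed in range(5):
            cfg = DEGSimConfig(
                n_genes=400, n_unique_a=0, n_unique_b=0, n_common=0, seed=seed
            )
            study = simulate_counts_and_degs(cfg)
            non_marker = study.deg_a[~study.deg_a["gene_id"].str.contains("MARK")]
            fp.append((non_marker["FDR"] < 0.1).sum())
        assert np.mean(fp) <= 0.1 * 400

    def test_common_genes_detected_in_both_tables(self):
        """Planted |logFC| 2.5 common genes reach FDR<0.1 in both transitions."""
        detected = total = 0
        for seed in range(10):
            study = simulate_counts_and_degs(DEGSimConfig(n_genes=400, seed=seed))
            common = study.truth[study.truth == "common"].index
            fdr_a = study.deg_a.set_index("gene_id")["FDR"]
            fdr_b = study.deg_b.set_index("gene_id")["FDR"]
            total += len(common)
            detected += sum((fdr_a[g] < 0.1) and (fdr_b[g] < 0.1) for g in common)
        assert detected / total >= 0.9

    def test_female_samples_have_zero_y_counts(self):
        study = simulate_counts_and_degs(DEGSimConfig(n_genes=200, seed=2))
        females = study.meta.loc[study.meta["sex"] == "F", "sample_id"]
        assert (study.counts.loc[study.y_markers, females] == 0).all().all()

    def test_deterministic_tables(self):
        cfg = DEGSimConfig(n_genes=200, seed=3)
        a = simulate_counts_and_degs(cfg)
        b = simulate_counts_and_degs(cfg)
        assert a.counts.equals(b.counts)
        assert a.deg_a.equals(b.deg_a)
        assert (a.truth == b.truth).all()
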