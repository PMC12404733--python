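"""Simulator: count model, read signatures, gene sets, determinism."""

import gzip

import numpy as np
import pytest

from wobbleseq.simulate import (
    CodonUsageModel,
    SimulationConfig,
    demo_config,
    simulate_counts,
    simulate_coupled_deltas,
    simulate_gene_sets,
    simulate_reads,
)


def _config(refset, **kw):
    defaults = dict(seed=5, n_replicates=3, reads_per_replicate=2000)
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestCounts:
    def test_alpha_zero_is_poisson(self, small_refset):
        # 100 replicates x 2 conditions = 200 draws per isodecoder
        cfg = _config(
            small_refset,
            n_replicates=100,
            dispersion=0.0,
            size_factor_sd=0.0,
            mean_abundance={i: 400.0 for i in small_refset.records},
        )
        counts, _ = simulate_counts(small_refset, cfg)
        sample_mean = counts.loc["Ala-AGC-1"].mean()
        se = np.sqrt(400.0 / counts.shape[1])
        assert abs(sample_mean - 400.0) < 3 * se
        # Poisson: variance close to mean (within 4 SE of s2 for n=200)
        s2 = counts.loc["Ala-AGC-1"].var()
        assert abs(s2 - 400.0) < 4 * 400.0 * np.sqrt(2 / counts.shape[1])

    def test_same_seed_identical(self, small_refset):
        c1, t1 = simulate_counts(small_refset, _config(small_refset))
        c2, t2 = simulate_counts(small_refset, _config(small_refset))
        assert c1.equals(c2)
        assert t1.size_factors == t2.size_factors

    def test_planted_log2fc_recorded(self, small_refset):
        fc = {m: -1.0 for m in small_refset.families[("Ala", "AGC")].members}
        cfg = _config(small_refset, log2fc=fc)
        _, truth = simulate_counts(small_refset, cfg)
        for m in fc:
            assert truth.log2fc_isodecoder[m] == -1.0
        assert truth.log2fc_family["Ala-AGC"] == pytest.approx(-1.0)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(seed=1, misinc_rate=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(seed=1, theta={"control": {"x": -0.1}})


def _wobble_bases(path, refset):
    """Wobble-position base per read, using the truth encoded in read names."""
    out = {}
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        lines = fh.read().splitlines()
    for i in range(0, len(lines), 4):
        name = lines[i][1:]
        seq = lines[i + 1]
        iso, start, idx = name.rsplit("|", 2)
        rec = refset.records[iso]
        w = rec.wobble_index - int(start)
        if rec.is_ann and w >= 0:
            out.setdefault(iso, []).append(seq[w])
    return out


class TestReads:
    @pytest.mark.parametrize("theta,expected", [(1.0, "G"), (0.0, "A")])
    def test_theta_extremes(self, small_refset, tmp_path, theta, expected):
        cfg = _config(
            small_refset,
            seq_error_rate=0.0,
            trunc_prob=0.0,
            theta={"control": {i: theta for i in small_refset.records}},
            mean_abundance={i: 50.0 for i in small_refset.records},
        )
        counts, _ = simulate_counts(small_refset, cfg)
        paths = simulate_reads(small_refset, counts[["control_1"]], cfg, tmp_path)
        for iso, bases in _wobble_bases(paths["control_1"], small_refset).items():
            assert set(bases) == {expected}

    def test_theta_binomial_convergence(self, small_refset, tmp_path):
        theta = 0.43  # magnitude of the most-affected isodecoder pool
        cfg = _config(
            small_refset,
            seq_error_rate=0.0,
            trunc_prob=0.0,
            theta={"control": {"Ala-AGC-1": theta}},
            mean_abundance={"Ala-AGC-1": 10_000.0},
            n_replicates=1,
        )
        counts, _ = simulate_counts(small_refset, cfg)
        paths = simulate_reads(small_refset, counts[["control_1"]], cfg, tmp_path,
                               gzip_output=False)
        bases = _wobble_bases(paths["control_1"], small_refset)["Ala-AGC-1"]
        g_frac = bases.count("G") / len(bases)
        tol = 3 * np.sqrt(theta * (1 - theta) / len(bases))
        assert abs(g_frac - theta) < tol

    def test_truncation_never_extends_past_site(self, small_refset, tmp_path):
        cfg = _config(
            small_refset,
            trunc_prob=0.5,
            mean_abundance={i: 200.0 for i in small_refset.records},
        )
        counts, _ = simulate_counts(small_refset, cfg)
        paths = simulate_reads(small_refset, counts[["control_1"]], cfg, tmp_path)
        with gzip.open(paths["control_1"], "rt") as fh:
            lines = fh.read().splitlines()
        starts = set()
        for i in range(0, len(lines), 4):
            iso, start, _ = lines[i][1:].rsplit("|", 2)
            start = int(start)
            rec = small_refset.records[iso]
            assert len(lines[i + 1]) == len(rec.sequence) - start
            # reads start either at 0 (full length) or just 3' of a mod site
            assert start == 0 or (start - 1) in {p for p, _ in rec.mod_sites}
            starts.add(start)
        assert len(starts) > 1  # truncation actually happened

    def test_same_seed_byte_identical_fastq(self, small_refset, tmp_path):
        cfg = _config(small_refset)
        counts, _ = simulate_counts(small_refset, cfg)
        p1 = simulate_reads(small_refset, counts, cfg, tmp_path / "a")
        p2 = simulate_reads(small_refset, counts, cfg, tmp_path / "b")
        for col in p1:
            with gzip.open(p1[col]) as f1, gzip.open(p2[col]) as f2:
                assert f1.read() == f2.read()


class TestCoupledDeltas:
    def test_target_rho_recovered_roughly(self):
        df = simulate_coupled_deltas(5000, 0.5, seed=9)
        from scipy.stats import spearmanr

        r = spearmanr(df["delta_i34_log2"], df["delta_abundance_log2"]).statistic
        assert abs(r - 0.5) < 0.05

    def test_invalid_rho(self):
        with pytest.raises(ValueError):
            simulate_coupled_deltas(10, 1.0, seed=0)


class TestGeneSets:
    def test_multiplier_one_is_null(self):
        cds, target, _ = simulate_gene_sets(
            CodonUsageModel(multiplier=1.0), seed=2, n_background=300, n_target=300
        )
        def gcc_share(ids):
            g = b = 0
            for i in ids:
                seq = cds[i]
                codons = [seq[k : k + 3] for k in range(0, len(seq), 3)]
                g += codons.count("GCC")
                b += sum(c in ("GCT", "GCC", "GCA") for c in codons)
            return g / b

        bg = [i for i in cds if i.startswith("bg")]
        assert abs(gcc_share(target) - gcc_share(bg)) < 0.02

    def test_multiplier_enriches_dependent_codon(self):
        cds, target, truth = simulate_gene_sets(
            CodonUsageModel(multiplier=1.5), seed=2, n_background=500, n_target=500
        )
        gcc = {"set": [0, 0], "bg": [0, 0]}
        for gid, seq in cds.items():
            key = "set" if gid.startswith("set") else "bg"
            codons = [seq[k : k + 3] for k in range(0, len(seq), 3)]
            gcc[key][0] += codons.count("GCC")
            gcc[key][1] += sum(c in ("GCT", "GCC", "GCA") for c in codons)
        set_share = gcc["set"][0] / gcc["set"][1]
        bg_share = gcc["bg"][0] / gcc["bg"][1]
        assert set_share > bg_share + 0.05
        assert truth.enrichment["multiplier"] == 1.5

    def test_bad_multiplier(self):
        with pytest.raises(ValueError):
            CodonUsageModel(multiplier=0.0)

    def test_seed_determinism(self):
        a, _, _ = simulate_gene_sets(CodonUsageModel(), seed=4, n_background=50,
                                     n_target=10)
        b, _, _ = simulate_gene_sets(CodonUsageModel(), seed=4, n_background=50,
                                     n_target=10)
        assert a == b


def test_demo_config_plants_paper_like_conditions(demo_refset):
    cfg = demo_config(demo_refset, seed=3)
    assert set(cfg.theta) == {"control", "patient"}
    assert all(v == 1.0 for v in cfg.theta["control"].values())
    ala = [i for i in cfg.theta["patient"] if i.startswith("Ala-AGC")]
    assert any(cfg.theta["patient"][i] < 1.0 for i in ala)
    # coupled units have both theta loss and planted abundance loss
    for iso in cfg.coupled_units:
        assert cfg.theta["patient"][iso] < 1.0
        assert cfg.log2fc[iso] < 0
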