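"""Synthetic-data generator: determinism, planted truth, calibration."""

import numpy as np
import pytest

from metstop.errors import ConfigError
from metstop.ptm_catalog import aggregate, parse_flank
from metstop.scoring import compute_stop_score
from metstop.sites import SITE_LABELS
from metstop.stats import paired_t
from metstop.synth import (
    SynthConfig,
    gen_domain_set,
    gen_feature_table,
    gen_ptm_table,
    make_windows,
    paired_t_rejection_rate,
    simulate_proportion_samples,
    write_domain_set,
)


class TestConfig:
    def test_defaults_validate(self):
        SynthConfig()

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_domains": 1},
            {"site_fraction": 0.0},
            {"site_fraction": 0.95},
            {"kr_density": 1.5},
            {"enrichment": -1.0},
            {"enrichment": 20.0, "base_mod_rate": 0.5},  # inside rate > 1
            {"study_count_law": ("zipf", 2.0)},
        ],
    )
    def test_infeasible_configs_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            SynthConfig(**kwargs)


class TestDomainSet:
    def test_same_seed_gives_byte_identical_outputs(self, tmp_path):
        config = SynthConfig(n_domains=10, seed=1)
        dirs = []
        for run in ("a", "b"):
            ds = gen_domain_set(config)
            write_domain_set(ds, tmp_path / run, ptms=gen_ptm_table(ds))
            dirs.append(tmp_path / run)
        for name in ("domains.fasta", "alignment.fasta", "sites.yaml", "truth.json", "ptms.tsv"):
            assert (dirs[0] / name).read_bytes() == (dirs[1] / name).read_bytes()

    def test_windows_cover_the_requested_fraction(self):
        windows = make_windows(120, 0.25)
        covered = sum(hi - lo + 1 for lo, hi in (windows.site1, windows.site2, windows.site3))
        assert covered == 30

    def test_truth_record_is_consistent_with_sequences(self):
        ds = gen_domain_set(SynthConfig(n_domains=20, seed=7))
        for mod in ds.truth["modifications"]:
            seq = ds.sequences[mod["domain"]]
            assert seq[mod["position"] - 1] == mod["residue"]
            assert mod["region"] in SITE_LABELS + ("outside",)

    def test_null_construction_plants_equal_rates(self):
        """With enrichment 1 the planted inside and outside per-residue
        modification rates agree in expectation."""
        ds = gen_domain_set(SynthConfig(n_domains=400, enrichment=1.0, seed=3))
        inv = ds.truth["per_domain"]
        p_in = sum(v["inside_modified"] for v in inv.values()) / sum(
            v["inside_kr"] for v in inv.values()
        )
        p_out = sum(v["outside_modified"] for v in inv.values()) / sum(
            v["outside_kr"] for v in inv.values()
        )
        assert p_in == pytest.approx(p_out, abs=0.02)

    def test_enriched_inside_rate_matches_law_of_large_numbers(self):
        """rho=3, base 0.1: empirical inside rate approaches 0.3."""
        ds = gen_domain_set(SynthConfig(n_domains=1000, seed=5))
        inv = ds.truth["per_domain"]
        total_in = sum(v["inside_kr"] for v in inv.values())
        mod_in = sum(v["inside_modified"] for v in inv.values())
        se = np.sqrt(0.3 * 0.7 / total_in)
        assert mod_in / total_in == pytest.approx(0.3, abs=4 * se)


class TestPTMTable:
    def test_every_emitted_record_validates(self):
        ds = gen_domain_set(SynthConfig(n_domains=30, seed=2))
        records = gen_ptm_table(ds)  # PTMRecord validates on construction
        assert len(records) == len(ds.truth["modifications"])
        for rec in records:
            letter, center = parse_flank(rec.flank)
            assert (letter, center) == (rec.residue_letter, 5)

    def test_constant_study_counts_give_unit_weights(self):
        config = SynthConfig(n_domains=20, seed=4, study_count_law=("constant", 1.0))
        ds = gen_domain_set(config)
        records = gen_ptm_table(ds)
        assert all(r.study_count == 1 for r in records)
        by_domain = {}
        for rec in records:
            by_domain.setdefault(rec.protein, []).append(rec)
        for name, recs in by_domain.items():
            score = compute_stop_score(ds.alignment[name], recs, ds.windows)
            in_site = [
                m for m in ds.truth["modifications"]
                if m["domain"] == name and m["region"] != "outside"
            ]
            assert score.total == len(in_site)

    def test_planted_counts_reproduce_weighted_score(self):
        """Three in-site modifications with study counts 1, 3 and 7 must
        recompute to a MET-stop score of 1 + 2 + 3 = 6."""
        ds = gen_domain_set(SynthConfig(n_domains=5, seed=6))
        name = next(iter(ds.sequences))
        seq = ds.sequences[name]
        windows = ds.windows
        site_positions = [
            pos for pos in range(1, len(seq) + 1)
            if windows.classify_column(pos) != "outside" and seq[pos - 1] in "KR"
        ][:3]
        assert len(site_positions) == 3, "fixture sequence lacks in-site K/R"
        mods = [
            {"domain": name, "position": pos, "residue": seq[pos - 1],
             "region": windows.classify_column(pos),
             "ptm_type": "methylation" if seq[pos - 1] == "R" else "acetylation",
             "study_count": count}
            for pos, count in zip(site_positions, (1, 3, 7))
        ]
        ds.truth["modifications"] = mods
        records = gen_ptm_table(ds)
        assert compute_stop_score(seq, records, windows).total == 6


class TestFeatureTable:
    def test_target_correlation_recovered_at_large_n(self):
        """The latent correlation is hit within Monte-Carlo error; the
        observable integer-valued columns show it attenuated toward zero by
        the truncation at 0 (which is why the truth record keeps the latent
        sample correlations)."""
        config = SynthConfig(n_domains=5000, feature_correlations={("mss", "pss"): 0.4})
        records, truth = gen_feature_table(config, seed=1)
        latent = np.array(truth["latent_sample_correlation"])
        assert latent[0, 1] == pytest.approx(0.4, abs=0.05)
        r = np.corrcoef([r.mss for r in records], [r.pss for r in records])[0, 1]
        assert 0.25 < r <= 0.45  # attenuated, same sign and order

    def test_null_table_shows_no_correlations(self):
        from metstop.stats import run_battery

        config = SynthConfig(n_domains=5000, feature_correlations={})
        records, _ = gen_feature_table(config, seed=2)
        report = run_battery(records)
        assert all(abs(c.r) < 0.1 for c in report.correlations.values())

    def test_non_positive_definite_target_rejected(self):
        bad = {("mss", "pss"): 0.9, ("lsi", "pss"): 0.9, ("lsi", "mss"): -0.9}
        with pytest.raises(ConfigError, match="positive-definite"):
            gen_feature_table(SynthConfig(feature_correlations=bad), seed=0)

    def test_tiny_table_generates_but_battery_rejects(self):
        from metstop.errors import DegenerateInputError
        from metstop.stats import pearson

        records, _ = gen_feature_table(SynthConfig(n_domains=2), seed=3)
        assert len(records) == 2
        with pytest.raises(DegenerateInputError):
            pearson([r.mss for r in records], [r.pss for r in records])


class TestCalibration:
    def test_vectorized_t_matches_reference_implementation(self):
        """One replicate of the calibration path agrees with paired_t."""
        config = SynthConfig(n_domains=50, seed=9)
        p_in, p_out = simulate_proportion_samples(config, 1, seed=9)
        keep = ~(np.isnan(p_in[0]) | np.isnan(p_out[0]))
        ref = paired_t(p_in[0][keep], p_out[0][keep])
        d = p_in[0][keep] - p_out[0][keep]
        t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert ref.t == pytest.approx(t, abs=1e-10)

    def test_type_i_error_near_nominal_under_null(self):
        rate = paired_t_rejection_rate(
            SynthConfig(enrichment=1.0, seed=101), n_replicates=1000
        )
        assert 0.03 <= rate <= 0.07

    def test_power_at_threefold_enrichment(self):
        rate = paired_t_rejection_rate(
            SynthConfig(enrichment=3.0, seed=102), n_replicates=500
        )
        assert rate >= 0.8
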