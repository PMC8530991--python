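"""Generator contracts: rounding, determinism, planted structure, NB means."""

import numpy as np
import pandas as pd
import pytest

from reciprotrace import synthetic as syn
from reciprotrace.errors import ConfigurationError


def _cfg(**kw):
    return syn.small_config(seed=5, **kw)


def _bare(n_genes, proportions, seed=1):
    """A config with no planted structure at all."""
    return syn.SyntheticConfig(
        n_genes=n_genes,
        type_proportions=proportions,
        planted_signatures={},
        planted_de_novo=syn.TracedSetPlan(totals={}, persistence=0.5),
        planted_shutdown=syn.TracedSetPlan(totals={}, persistence=0.5),
        universe_sizes={t: n_genes for t in syn.TIMEPOINTS},
        atac_maintenance=(),
        seed=seed,
    )


class TestAnnotation:
    def test_single_type_degenerate(self):
        ann = syn.generate_annotation(_bare(10, {"protein_coding": 1.0}))
        assert len(ann) == 10
        assert (ann["gene_type"] == "protein_coding").all()

    def test_largest_remainder_counts(self):
        cfg = _bare(1000, {"protein_coding": 0.5, "pseudogene": 0.3, "non_annotated": 0.2})
        ann = syn.generate_annotation(cfg)
        counts = ann["gene_type"].value_counts().to_dict()
        assert counts == {"protein_coding": 500, "pseudogene": 300, "non_annotated": 200}

    def test_seed_determinism_byte_identical(self, tmp_path):
        cfg = _cfg()
        a = syn.generate_annotation(cfg)
        b = syn.generate_annotation(cfg)
        pa, pb = tmp_path / "a.tsv", tmp_path / "b.tsv"
        a.to_csv(pa, sep="\t", index=False)
        b.to_csv(pb, sep="\t", index=False)
        assert pa.read_bytes() == pb.read_bytes()

    def test_mt_bijection_and_no_y(self, small_dataset):
        ann = small_dataset[0]
        mito = ann["gene_type"] == "mitochondrial"
        on_mt = ann["chromosome"] == "MT"
        assert (mito == on_mt).all()
        assert not (ann["chromosome"] == "Y").any()

    def test_invalid_proportions_rejected(self):
        cfg = _cfg()
        cfg.type_proportions = {"protein_coding": 0.5, "pseudogene": 0.4}
        with pytest.raises(ConfigurationError, match="sum to 1"):
            syn.generate_annotation(cfg)


class TestLargestRemainder:
    def test_exact_apportionment(self):
        assert syn.largest_remainder(1000, [0.5, 0.3, 0.2]) == [500, 300, 200]

    def test_ties_broken_by_name_order(self):
        # 3 items over two equal weights: .5 remainders; 'a' wins the extra
        assert syn.largest_remainder(3, [1, 1], ["b", "a"]) == [1, 2]

    @pytest.mark.parametrize("total,weights", [(7, [1, 2, 3]), (0, [1, 1]), (13, [5, 1, 1, 1])])
    def test_sums_to_total(self, total, weights):
        assert sum(syn.largest_remainder(total, weights)) == total


class TestCounts:
    def test_nb_mean_centering_low_dispersion(self):
        # dispersion -> 0, no effect: condition mean ~= baseline within 5% at n=1000
        cfg = _bare(50, syn._default_type_proportions())
        cfg.baseline_mean_log_range = (100.0, 1000.0)
        cfg.nb_dispersion = 0.0
        cfg.n_replicates = 1000
        cfg.size_factor_range = (1.0, 1.0)
        counts, _ = syn.generate_counts(cfg)
        c = counts["d0"]
        mock = c[[f"mock_{i+1}" for i in range(1000)]].mean(axis=1)
        cond = c[[f"cond_{i+1}" for i in range(1000)]].mean(axis=1)
        keep = mock >= 100
        rel = np.abs(cond[keep] - mock[keep]) / mock[keep]
        assert (rel < 0.05).all()

    def test_planted_de_novo_zero_pattern(self, small_cfg):
        counts, truth = syn.generate_counts(small_cfg)
        for tp, c in counts.items():
            mock_cols = [col for col in c.columns if col.startswith("mock")]
            cond_cols = [col for col in c.columns if col.startswith("cond")]
            zero_mock = set(c.index[c[mock_cols].sum(axis=1) == 0])
            zero_cond = set(c.index[c[cond_cols].sum(axis=1) == 0])
            assert zero_mock == truth.de_novo_flagged[tp]
            assert zero_cond == truth.shutdown_flagged[tp]
            # expressed side never all-zero
            assert not (truth.de_novo_flagged[tp] & zero_cond)

    def test_ground_truth_seed_determinism(self, small_cfg):
        _, t1 = syn.generate_counts(small_cfg)
        _, t2 = syn.generate_counts(small_cfg)
        assert t1.signatures == t2.signatures
        assert t1.de_novo_flagged == t2.de_novo_flagged
        assert t1.shutdown_first == t2.shutdown_first


class TestTables:
    def test_planted_ids_exist_in_annotation(self, small_dataset):
        ann, tables, _, _, truth = small_dataset
        all_ids = set(ann["gene_id"])
        for ids in truth.signatures.values():
            assert ids <= all_ids
        for ids in truth.de_novo_flagged.values():
            assert ids <= all_ids

    def test_universe_sizes(self, small_cfg, small_dataset):
        _, tables, _, _, _ = small_dataset
        for tp, df in tables.items():
            assert len(df) == small_cfg.universe_sizes[tp]
            assert not df["gene_id"].duplicated().any()

    def test_planted_sets_within_timepoint_disjoint(self, small_dataset):
        _, _, _, _, truth = small_dataset
        for tp in ("d0", "d3", "d12", "d28"):
            up = truth.signatures[(tp, "up")]
            down = truth.signatures[(tp, "down")]
            dn = truth.de_novo_flagged[tp]
            sd = truth.shutdown_flagged[tp]
            assert not (up & down) and not (dn & sd)
            assert not ((up | down) & (dn | sd))

    def test_atac_direction_agreement_matches_coupling(self, small_cfg, small_dataset):
        _, _, atac, _, truth = small_dataset
        agree = total = 0
        planted_dir = {}
        for (tp, d), ids in truth.signatures.items():
            for g in ids:
                planted_dir[(tp, g)] = 1 if d == "up" else -1
        for tp, df in atac.items():
            fc = df.set_index("gene_id")["log2fc"]
            for g, sgn in truth.accessibility_direction.items():
                if (tp, g) in planted_dir and g in fc.index:
                    total += 1
                    if np.sign(fc.loc[g]) == planted_dir[(tp, g)]:
                        agree += 1
        assert total > 0
        # exact-count coupling: the agreement rate is the configured value +-1/n
        assert agree / total == pytest.approx(small_cfg.atac_coupling, abs=0.05)

    def test_persistence_totals_reproduced(self, small_cfg, small_dataset):
        _, _, _, _, truth = small_dataset
        for tp, total in small_cfg.planted_de_novo.totals.items():
            assert len(truth.de_novo_flagged[tp]) == total
        for tp, total in small_cfg.planted_shutdown.totals.items():
            assert len(truth.shutdown_flagged[tp]) == total

    def test_incompatible_persistence_rejected(self):
        cfg = _cfg()
        cfg.planted_de_novo = syn.TracedSetPlan(
            totals={"d0": 100, "d3": 10}, persistence=0.9)
        with pytest.raises(ConfigurationError, match="persistence"):
            syn.generate_diff_tables(cfg)

    def test_effect_overflow_rejected(self):
        cfg = _cfg()
        cfg.planted_signatures = {
            ("d0", "up"): syn.SignaturePlan(
                (syn.ClassAllocation("protein_coding", 1, 1e18),), log2_effect=40.0)}
        with pytest.raises(ConfigurationError, match="overflow"):
            cfg.validate()


class TestConfigRoundTrip:
    def test_yaml_round_trip(self, tmp_path, small_cfg):
        p = tmp_path / "cfg.yaml"
        syn.save_config(small_cfg, p)
        again = syn.load_config(p)
        assert again == small_cfg
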