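import json

import pytest

from fixiscan.architecture import Variant, call_variants
from fixiscan.context import extract_all_contexts
from fixiscan.errors import ConfigError, ValidationError
from fixiscan.markers import Classification, classify_cluster
from fixiscan.pipeline import PipelineConfig, run_classify, read_genome_summaries
from fixiscan.records import group_by_genome
from fixiscan.simulate import (
    SimConfig,
    SyntheticTruth,
    generate_dataset,
    truth_compare,
    write_dataset,
)

SMALL = dict(n_orders=3, genomes_per_order=5, genes_per_contig=(15, 25))


def run_pipeline_on(dataset, tmp_path, **cfg_kw):
    paths = write_dataset(dataset, tmp_path / "data")
    cfg = PipelineConfig(
        genes=str(paths["genes"]),
        domain_hits=str(paths["domain_hits"]),
        taxonomy=str(paths["taxonomy"]),
        tree=str(paths["tree"]),
        out_dir=str(tmp_path / "out"),
        **cfg_kw,
    )
    outputs = run_classify(cfg)
    calls = call_variants(
        __import__("fixiscan.io", fromlist=["read_domain_hits"]).read_domain_hits(
            paths["domain_hits"]
        )
    )
    positive = [c for c in calls.values() if c.variant is not Variant.NONE]
    contexts = extract_all_contexts(dataset.genes, positive)
    cluster_calls = [classify_cluster(cl, v) for cl, v in contexts]
    summaries = read_genome_summaries(outputs["genome_summaries"])
    return calls, cluster_calls, summaries


class TestDeterminism:
    def test_same_seed_byte_identical_files(self, tmp_path):
        cfg = SimConfig(seed=42, **SMALL)
        p1 = write_dataset(generate_dataset(cfg), tmp_path / "a")
        p2 = write_dataset(generate_dataset(cfg), tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes(), key

    def test_different_seeds_differ(self, tmp_path):
        d1 = generate_dataset(SimConfig(seed=1, **SMALL))
        d2 = generate_dataset(SimConfig(seed=2, **SMALL))
        assert d1.newick != d2.newick


class TestPlantedStructure:
    def test_truth_tallies_match_planted_genes(self):
        ds = generate_dataset(SimConfig(seed=7, **SMALL))
        by_genome = group_by_genome(ds.genes)
        planted_per_genome = {}
        for a in ds.truth.atpases:
            planted_per_genome.setdefault(a.genome_id, []).append(a)
        for gid, gt in ds.truth.genomes.items():
            planted = planted_per_genome.get(gid, [])
            for variant, n in gt.copy_number.items():
                assert sum(1 for a in planted if a.variant == variant) == n
            marker_genes = [g for g in by_genome[gid] if g.labels]
            assert (len(marker_genes) > 0) == gt.cbb3_present

    def test_point_mass_at_zero_copies_gives_empty_genomes(self, tmp_path):
        cfg = SimConfig(
            seed=3,
            copy_number_probs={
                Variant.ONE_DOMAIN.value: (1.0,),
                Variant.TWO_DOMAIN.value: (1.0,),
            },
            **SMALL,
        )
        ds = generate_dataset(cfg)
        assert ds.truth.atpases == []
        _, _, summaries = run_pipeline_on(ds, tmp_path)
        for s in summaries:
            assert s.copy_number == {"ONE_DOMAIN": 0, "TWO_DOMAIN": 0}

    def test_full_colocalization_all_one_domain_fixi_like(self, tmp_path):
        cfg = SimConfig(seed=11, p_fixi_colocalization=1.0, **SMALL)
        ds = generate_dataset(cfg)
        _, cluster_calls, _ = run_pipeline_on(ds, tmp_path)
        by_pid = {cc.variant.protein_id: cc for cc in cluster_calls}
        one_domain = [a for a in ds.truth.atpases if a.variant == "ONE_DOMAIN"]
        assert one_domain, "expected some planted 1-domain ATPases"
        for a in one_domain:
            assert by_pid[a.protein_id].classification is Classification.FIXI_LIKE

    def test_infeasible_contig_size_rejected_before_output(self):
        with pytest.raises(ConfigError):
            generate_dataset(SimConfig(genes_per_contig=(2, 3)))

    def test_decoy_pool_collision_rejected(self):
        with pytest.raises(ConfigError):
            generate_dataset(SimConfig(decoy_domain_pool=("PF00403",)))


class TestTruthCompare:
    def test_noiseless_run_has_zero_mismatches(self, tmp_path):
        ds = generate_dataset(SimConfig(seed=5, **SMALL))
        calls, cluster_calls, summaries = run_pipeline_on(ds, tmp_path)
        assert truth_compare(ds.truth, calls, cluster_calls, summaries) == []

    def test_incomplete_signature_decoy_is_ignored_in_exact_mode(self, tmp_path):
        from fixiscan.records import DomainHit

        ds = generate_dataset(SimConfig(seed=5, **SMALL))
        # add an incomplete-signature decoy (PF00403-PF00122 only) to a filler protein
        victim = next(
            g.protein_id for g in ds.genes if not g.labels and g.protein_id not in ds.domain_hits
        )
        ds.domain_hits[victim] = [
            DomainHit(victim, "PF00403", 5, 70, 1e-20),
            DomainHit(victim, "PF00122", 120, 300, 1e-30),
        ]
        calls, cluster_calls, summaries = run_pipeline_on(ds, tmp_path)
        assert truth_compare(ds.truth, calls, cluster_calls, summaries) == []

    def test_genome_id_space_mismatch_is_error(self, tmp_path):
        ds = generate_dataset(SimConfig(seed=5, **SMALL))
        calls, cluster_calls, summaries = run_pipeline_on(ds, tmp_path)
        with pytest.raises(ValidationError):
            truth_compare(ds.truth, calls, cluster_calls, summaries[1:])


class TestTruthSerialization:
    def test_json_round_trip(self, tmp_path):
        ds = generate_dataset(SimConfig(seed=9, **SMALL))
        p = tmp_path / "truth.json"
        ds.truth.to_json(p)
        loaded = SyntheticTruth.from_json(p)
        assert loaded.genomes == ds.truth.genomes
        assert loaded.atpases == ds.truth.atpases
        json.loads(p.read_text())  # valid JSON


class TestScrambledOrders:
    def test_scramble_breaks_monophyly(self, tmp_path):
        from fixiscan.aggregate import collapse_to_rank
        from fixiscan.io import tree_from_string

        ds = generate_dataset(SimConfig(seed=13, scramble_orders=True, **SMALL))
        tree = tree_from_string(ds.newick)
        collapsed = collapse_to_rank(tree, ds.taxonomy)
        labels = {lf.taxon.label for lf in collapsed.leaf_node_iter()}
        assert any("_2" in lab for lab in labels)
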