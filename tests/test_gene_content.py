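"""Gene-status classification, category counts, staging, comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from organellekit import gene_content as gc
from organellekit import synthetic_data as syn
from organellekit._align import translate


def _cds(n_codons, rng=None):
    rng = rng or np.random.default_rng(0)
    return syn._random_cds(rng, 3 * n_codons)


class TestClassifyGene:
    def test_identical_sequence_is_intact(self):
        ref = _cds(100)
        gs = gc.classify_gene(ref, ref)
        assert (gs.status, gs.reason) == (gc.Status.INTACT, gc.Reason.OK)

    def test_stop_at_codon_40_of_100_is_premature(self):
        ref = _cds(100)
        obs = ref[: 39 * 3] + "TAA" + ref[40 * 3 :]
        gs = gc.classify_gene(obs, ref)
        assert (gs.status, gs.reason) == (
            gc.Status.PSEUDOGENE,
            gc.Reason.PREMATURE_STOP,
        )

    def test_absent_gene_is_lost(self):
        gs = gc.classify_gene(None, _cds(100))
        assert (gs.status, gs.reason) == (gc.Status.LOST, gc.Reason.NO_HIT)

    def test_truncation_below_half_is_too_short(self):
        ref = _cds(100)
        gs = gc.classify_gene(ref[:120], ref)
        assert (gs.status, gs.reason) == (gc.Status.PSEUDOGENE, gc.Reason.TOO_SHORT)

    def test_heavy_divergence_with_conserved_anchor(self):
        # one conserved stretch keeps the gene detectable while the rest
        # has diverged beyond recognition -> excess_divergence
        rng = np.random.default_rng(7)
        ref = _cds(120)
        scrambled = syn._random_cds(rng, len(ref))
        obs = ref[:90] + scrambled[90:]
        gs = gc.classify_gene(obs, ref, gc.ClassifyParams(tau_id=0.8))
        assert gs.status is gc.Status.PSEUDOGENE
        assert gs.reason in (gc.Reason.EXCESS_DIVERGENCE, gc.Reason.PREMATURE_STOP)

    def test_unrelated_sequence_is_lost(self):
        rng = np.random.default_rng(11)
        ref = _cds(100)
        assert gc.classify_gene(syn._random_seq(rng, 300), ref).status is gc.Status.LOST

    def test_structural_rna_skips_stop_test(self):
        rng = np.random.default_rng(3)
        ref = syn._random_seq(rng, 120)
        # internal TAA triplets are irrelevant for an rRNA
        obs = ref[:30] + "TAA" + ref[33:]
        gs = gc.classify_gene(obs, ref, structural_rna=True)
        assert gs.status is gc.Status.INTACT

    def test_errors(self):
        with pytest.raises(ValueError, match="empty"):
            gc.classify_gene("ATG", "")
        with pytest.raises(ValueError, match="non-nucleotide"):
            gc.classify_gene("ATGXX!", "ATGTAA")

    def test_agrees_with_bruteforce_oracle_on_small_catalog(self):
        """Independent re-derivation: direct length/frame/stop checks."""
        rng = np.random.default_rng(17)
        params = gc.ClassifyParams()
        for _ in range(20):
            ref = _cds(int(rng.integers(40, 120)))
            kind = rng.choice(["intact", "stop", "trunc", "absent"])
            if kind == "absent":
                obs = None
            elif kind == "trunc":
                obs = ref[: int(0.4 * len(ref))]
            elif kind == "stop":
                i = int(rng.integers(5, len(ref) // 3 - 5))
                obs = ref[: 3 * i] + "TAA" + ref[3 * i + 3 :]
            else:
                obs = ref
            got = gc.classify_gene(obs, ref, params)
            # oracle
            if obs is None:
                want = (gc.Status.LOST, gc.Reason.NO_HIT)
            elif len(obs) < params.tau_len * len(ref):
                want = (gc.Status.PSEUDOGENE, gc.Reason.TOO_SHORT)
            elif "*" in translate(obs)[: len(ref) // 3 - 1]:
                want = (gc.Status.PSEUDOGENE, gc.Reason.PREMATURE_STOP)
            else:
                want = (gc.Status.INTACT, gc.Reason.OK)
            assert (got.status, got.reason) == want, kind


class TestCatalogCounts:
    def test_fixture_counts_68_intact_11_pseudogenes(self, classified):
        counts = gc.count_by_status(classified, per_symbol=True)
        assert counts["intact"] == 68
        assert counts["pseudogene"] == 11
        assert counts["lost"] == 40

    def test_intact_summary_breakdown(self, classified):
        counts = gc.count_by_status(classified, per_symbol=True, summary=True)
        assert counts["by_category"]["intact"] == {
            "trn": 31, "rrn": 8, "rps": 10, "rpl": 7, "other": 12
        }

    def test_statuses_partition_the_catalog(self, classified):
        counts = gc.count_by_status(classified, per_symbol=True)
        assert counts["intact"] + counts["pseudogene"] + counts["lost"] == counts["total"]

    def test_empty_catalog_all_zero(self):
        counts = gc.count_by_status(pd.DataFrame(columns=["gene", "copy", "category", "status"]))
        assert (counts["intact"], counts["pseudogene"], counts["lost"]) == (0, 0, 0)

    def test_classification_recovers_planted_statuses(self, classified, spec):
        by_symbol = gc.collapse_copies(classified).set_index("gene")["status"]
        for gene, status in spec.gene_statuses.items():
            assert by_symbol[gene] == status, gene


class TestCoreRetention:
    def test_fixture_mito_retains_all_24_core_genes(self, mitogenome):
        _, catalog, _ = mitogenome
        result = gc.check_core_retention(catalog)
        assert result["core_present"] == 24
        assert result["core_missing"] == []
        assert {"rps2", "rps11"} <= set(result["variable_missing"])

    def test_deleting_nad5_is_reported(self, mitogenome):
        _, catalog, _ = mitogenome
        pruned = gc.GeneCatalog(
            genes=[g for g in catalog if g.name != "nad5"],
            replicon_lengths=catalog.replicon_lengths,
        )
        result = gc.check_core_retention(pruned)
        assert result["core_present"] == 23
        assert result["core_missing"] == ["nad5"]

    def test_default_core_roster_has_24_symbols(self):
        assert len(gc.DEFAULT_MITO_CORE) == 24

    def test_empty_core_list_rejected(self, mitogenome):
        _, catalog, _ = mitogenome
        with pytest.raises(ValueError):
            gc.check_core_retention(catalog, core_list=set())


STAGE_CATS = ("psa", "psb", "pet", "ndh", "rpo", "atp", "rps", "rpl", "rbcL")


class TestStaging:
    def test_all_intact_is_photosynthetic(self):
        profile = {c: (5, 5) for c in STAGE_CATS}
        assert gc.assign_stage(profile) is gc.DegradationStage.PHOTOSYNTHETIC

    def test_fixture_profile_is_stationary(self, classified):
        profile = gc.profile_from_classification(classified)
        assert gc.assign_stage(profile) is gc.DegradationStage.STATIONARY

    def test_half_degraded_photosystems_is_degradation_one(self):
        profile = {
            "psa": (2, 4), "psb": (7, 14), "pet": (6, 6), "ndh": (0, 11),
            "rpo": (0, 4), "atp": (6, 6), "rps": (12, 12), "rpl": (8, 8),
            "rbcL": (1, 1),
        }
        assert gc.assign_stage(profile) is gc.DegradationStage.DEGRADATION_I

    def test_no_plastome_is_absent(self):
        assert gc.assign_stage(None) is gc.DegradationStage.ABSENT

    def test_housekeeping_decay_is_degradation_two(self):
        profile = {c: (0, 5) for c in STAGE_CATS}
        assert gc.assign_stage(profile) is gc.DegradationStage.DEGRADATION_II

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            gc.assign_stage({"atp": (7, 5)})

    @settings(max_examples=200, derandomize=True)
    @given(st.data())
    def test_stage_monotone_under_additional_degradation(self, data):
        """Degrading one more gene never moves the stage earlier."""
        profile = {}
        for cat in STAGE_CATS:
            total = data.draw(st.integers(1, 12), label=cat)
            intact = data.draw(st.integers(0, total), label=f"{cat}_intact")
            profile[cat] = (intact, total)
        before = gc.assign_stage(profile)
        degradable = [c for c in STAGE_CATS if profile[c][0] > 0]
        if not degradable:
            return
        cat = data.draw(st.sampled_from(degradable), label="degrade")
        profile[cat] = (profile[cat][0] - 1, profile[cat][1])
        assert gc.assign_stage(profile) >= before


class TestGenBankInput:
    def test_catalog_from_genbank_flat_file(self, tmp_path):
        from Bio.Seq import Seq
        from Bio.SeqFeature import FeatureLocation, SeqFeature
        from Bio.SeqRecord import SeqRecord
        from Bio import SeqIO

        rng = np.random.default_rng(2)
        gene = syn._random_cds(rng, 300)
        genome = syn._random_seq(rng, 200) + gene + syn._random_seq(rng, 100)
        rec = SeqRecord(Seq(genome), id="toy", annotations={"molecule_type": "DNA"})
        rec.features.append(
            SeqFeature(
                FeatureLocation(200, 500, strand=1),
                type="gene",
                qualifiers={"gene": ["psbA"]},
            )
        )
        path = tmp_path / "toy.gb"
        SeqIO.write([rec], str(path), "genbank")

        catalog = gc.read_genbank(path)
        assert catalog.replicon_lengths == {"toy": 600}
        (record,) = catalog.by_name("psbA")
        assert (record.start, record.end, record.category) == (200, 500, "psb")
        assert record.sequence == gene


class TestCompareContent:
    def test_printed_rhinantheae_ratios(self):
        matrix = syn.make_content_matrix()
        out = gc.compare_content(matrix, "Melampyrum_koreanum", "Lathraea_squamaria")
        assert (out["lost_a"], out["lost_b"]) == (7, 5)
        assert out["lost_pct_of_a"] == 71.4
        assert (out["pseudo_a"], out["pseudo_b"]) == (4, 30)
        assert out["pseudo_pct_of_a"] == 750.0  # 7.5x

    def test_self_comparison_is_100_percent(self):
        matrix = syn.make_content_matrix()
        out = gc.compare_content(matrix, "Aeginetia_indica", "Aeginetia_indica")
        assert out["lost_pct_of_a"] == 100.0
        assert out["pseudo_pct_of_a"] == 100.0

    def test_zero_baseline_reported_as_undefined(self):
        matrix = syn.make_content_matrix()
        out = gc.compare_content(
            matrix, "Lindenbergia_philippensis", "Christisonia_kwangtungensis"
        )
        assert out["lost_a"] == 0 and out["lost_pct_of_a"] is None

    def test_unknown_species_raises(self):
        with pytest.raises(KeyError):
            gc.compare_content(syn.make_content_matrix(), "Nope", "Aeginetia_indica")
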