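import json

import pytest

from pseudotrace.formats_io import RunConfig, write_report_json
from pseudotrace.orchestrator import (StudyInputs, restrict_species_tree,
                                      run_batch, run_study, write_outputs)
from pseudotrace.synth_data import PlantedEvent


class TestRestriction:
    def test_names_preserved_and_unary_suppressed(self, tree5):
        sub = restrict_species_tree(tree5, ["Hsa", "Mmu", "Mus"])
        names = {n.name for n in sub.preorder()}
        assert {"Hsa", "Mmu", "Mus", "Ctr", "Eth"} <= names
        for n in sub.preorder():
            assert n.is_leaf or len(n.children) == 2


class TestSimpleMode:
    def test_planted_loss_detected_without_genomes(self, study_factory):
        study = study_factory(seed=21, rate=0.03,
                              events=[PlantedEvent(("Hpa", "Hsa"), "loss")])
        inputs = StudyInputs.from_simulated(study)
        cfg = RunConfig(ancestor="Eth", mode="simple")
        rep = run_study(cfg, inputs)
        assert rep.verdicts["Hsa"] == "Lost"
        assert all(v == "Present" for sp, v in rep.verdicts.items()
                   if sp != "Hsa")
        assert (("Hpa", "Hsa")) in [e.branch for e in rep.events]


class TestCompleteMode:
    def test_terminal_loss(self, study_factory):
        study = study_factory(seed=22, rate=0.02,
                              events=[PlantedEvent(("Mur", "Rno"), "loss")])
        rep = run_study(RunConfig(ancestor="Eth"),
                        StudyInputs.from_simulated(study))
        assert rep.verdicts == {"Hsa": "Present", "Ptr": "Present",
                                "Mmu": "Present", "Mus": "Present",
                                "Rno": "Lost"}
        assert [(e.branch, e.event) for e in rep.events] == \
               [(("Mur", "Rno"), "gene_loss")]

    def test_pseudogene_with_planted_mutations_at_rate_zero(self,
                                                            study_factory):
        study = study_factory(
            seed=23, rate=0.0,
            events=[PlantedEvent(("Hpa", "Hsa"), "pseudogenization",
                                 (("nonsense",), ("nonsense",)))])
        rep = run_study(RunConfig(ancestor="Eth"),
                        StudyInputs.from_simulated(study))
        assert rep.verdicts["Hsa"] == "Pseudogene"
        ev = [e for e in rep.events if e.event == "pseudogenization"]
        assert len(ev) == 1 and ev[0].branch == ("Hpa", "Hsa")
        truth = {(m.kind, m.exon_index, m.position)
                 for _, _, muts in study.ledger.events for m in muts}
        got = {(m.kind, m.exon_index, m.position)
               for m in ev[0].supporting_mutations}
        assert truth <= got

    def test_unannotated_gene_is_saved(self, study_factory):
        study = study_factory(seed=24, rate=0.02, unannotated={"Mmu"})
        rep = run_study(RunConfig(ancestor="Eth"),
                        StudyInputs.from_simulated(study))
        assert rep.verdicts["Mmu"] == "Saved"
        assert not rep.events

    def test_verdict_partition_invariant(self, study_factory):
        study = study_factory(
            seed=25, rate=0.02, unannotated={"Mmu"},
            events=[PlantedEvent(("Mur", "Rno"), "loss"),
                    PlantedEvent(("Hpa", "Hsa"), "pseudogenization",
                                 (("insertion", 4),))])
        inputs = StudyInputs.from_simulated(study)
        rep = run_study(RunConfig(ancestor="Eth"), inputs)
        scope = inputs.species_tree.species_under("Eth")
        assert set(rep.verdicts) == scope
        allowed = {"Present", "Saved", "Pseudogene", "Lost", "Unresolved"}
        assert set(rep.verdicts.values()) <= allowed

    def test_determinism_byte_identical_reports(self, study_factory,
                                                tmp_path):
        study = study_factory(
            seed=26, rate=0.02,
            events=[PlantedEvent(("Hpa", "Hsa"), "pseudogenization",
                                 (("nonsense",),))])
        blobs = []
        for run_dir in ("r1", "r2"):
            rep = run_study(RunConfig(ancestor="Eth"),
                            StudyInputs.from_simulated(study))
            p = tmp_path / f"{run_dir}.json"
            write_report_json(rep.to_dict(), p)
            blobs.append(p.read_bytes())
        assert blobs[0] == blobs[1]

    def test_excluded_annotation_triggers_reannotation(self, study_factory):
        """Excluding a gene id makes the pipeline re-derive the species
        verdict from the genome instead of trusting the annotation."""
        study = study_factory(seed=27, rate=0.02)
        inputs = StudyInputs.from_simulated(study)
        cfg = RunConfig(ancestor="Eth", excluded_gene_ids={"Rno|g1"})
        rep = run_study(cfg, inputs)
        # the intact gene is rediscovered from the genome: Saved, not Lost
        assert rep.verdicts["Rno"] in ("Saved", "Present")
        assert not [e for e in rep.events if e.event == "gene_loss"]


class TestOutputs:
    def test_write_outputs_round_trip(self, study_factory, tmp_path):
        from pseudotrace.formats_io import read_annotated_tree
        study = study_factory(seed=28, rate=0.0,
                              events=[PlantedEvent(("Mur", "Rno"), "loss")])
        inputs = StudyInputs.from_simulated(study)
        rep = run_study(RunConfig(ancestor="Eth"), inputs)
        write_outputs(rep, inputs.species_tree, tmp_path)
        data = json.loads((tmp_path / "report.json").read_text())
        assert data["verdicts"]["Rno"] == "Lost"
        _, states, events, birth = read_annotated_tree(tmp_path / "events.nhx")
        assert states["Rno"] == "Lost"
        assert [tuple(e.branch) for e in events] == [("Mur", "Rno")]
        assert (tmp_path / "mutations.tsv").exists()


class TestBatch:
    def test_failures_isolated(self, study_factory):
        study = study_factory(seed=29, rate=0.02)
        good = (RunConfig(ancestor="Eth", mode="simple"),
                StudyInputs.from_simulated(study))
        bad = (RunConfig(ancestor="NotANode", mode="simple"),
               StudyInputs.from_simulated(study))
        out = run_batch([good, bad])
        assert len(out) == 2
        assert hasattr(out[0], "verdicts")
        assert isinstance(out[1], dict) and "error" in out[1]

    def test_empty_batch(self):
        assert run_batch([]) == []


class TestSubfamilyScan:
    def test_duplicated_family_reports_subfamily_losses(self, tree5):
        """With the lineage-scan option on, each sub-family established by a
        speciation after a duplication is reported with its own missing
        species."""
        import numpy as np

        from pseudotrace.formats_io import RunConfig, SequenceRecord

        rng = np.random.default_rng(3)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        base = list("MKVLIEQWRAGDNSTYFPHC" * 4)
        copy2 = base.copy()
        for pos in rng.integers(0, len(copy2), 25):  # diverged paralog family
            copy2[pos] = aas[int(rng.integers(0, 20))]

        def tweak(seq, n):
            out = seq.copy()
            for pos in rng.integers(0, len(out), n):
                out[pos] = aas[int(rng.integers(0, 20))]
            return "".join(out)

        proteomes = {}
        for sp in tree5.leaf_names:
            recs = [SequenceRecord(f"{sp}|c1", sp, tweak(base, 3), "protein")]
            if sp != "Hsa":  # copy 2 lost in human
                recs.append(SequenceRecord(f"{sp}|c2", sp, tweak(copy2, 3),
                                           "protein"))
            proteomes[sp] = recs
        query = proteomes["Mmu"][1]
        inputs = StudyInputs(species_tree=tree5, query=query,
                             proteomes=proteomes)
        cfg = RunConfig(ancestor="Eth", mode="simple", scan_subfamilies=True)
        rep = run_study(cfg, inputs)
        assert rep.subfamilies, "lineage scan should report sub-families"
        all_missing = {sp for sub in rep.subfamilies
                       for sp in sub["missing_species"]}
        assert "Hsa" in all_missing
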