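"""CO-dehydrogenase motif scanning, operon detection and form calls."""

import numpy as np
import pytest

from ventplume import codh, synth
from ventplume.codh import (
    AlphabetError,
    AnnotatedGene,
    MissingProteinError,
    classify_genome,
    classify_operon,
    detect_operons,
    scan_motif,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def brute_force_scan(seq):
    """Independent sliding-window oracle for the motif scanner."""
    seq = seq.upper()
    for i in range(len(seq) - 6):
        w = seq[i : i + 7]
        if w == "AYRGAGR":
            return ("form_II", i + 1)
        if (
            w[0] == "A" and w[1] == "Y" and w[3] == "C"
            and w[4] == "S" and w[5] == "F" and w[6] == "R"
        ):
            return ("form_I", i + 1)
    return None


class TestScanMotif:
    def test_form_ii_exact(self):
        m = scan_motif("MKAYRGAGRLV")
        assert m.form == "form_II" and m.motif == "AYRGAGR" and m.position == 3

    def test_form_i_wildcard_accepts_x(self):
        m = scan_motif("GGAYXCSFRGG")
        assert m.form == "form_I" and m.position == 3

    def test_no_motif(self):
        assert scan_motif("MKLVNNNNNNPQ") is None

    def test_illegal_characters(self):
        with pytest.raises(AlphabetError):
            scan_motif("MKAY*GAGR")

    def test_first_match_wins(self):
        m = scan_motif("AYACSFR" + "AYRGAGR")
        assert m.form == "form_I" and m.position == 1

    def test_against_brute_force_oracle(self):
        rng = np.random.default_rng(1234)
        motifs = ["AYRGAGR", "AYGCSFR", "AYXCSFR", ""]
        for trial in range(300):
            seq = "".join(rng.choice(list(AA), size=60))
            motif = motifs[trial % len(motifs)]
            if motif:
                pos = int(rng.integers(0, 54))
                seq = seq[:pos] + motif + seq[pos + 7:]
            expected = brute_force_scan(seq)
            got = scan_motif(seq)
            if expected is None:
                assert got is None
            else:
                assert (got.form, got.position) == expected


def gene(contig, start, length, role, pid, strand="+"):
    return AnnotatedGene(contig, start, start + length - 1, strand, role, pid)


class TestDetectOperons:
    def test_slm_cluster_one_operon(self):
        genes = [
            gene("c", 100, 900, "coxS", "s"),
            gene("c", 1050, 2400, "coxL", "l"),
            gene("c", 3500, 800, "coxM", "m"),
        ]
        ops = detect_operons(genes)
        assert len(ops) == 1
        assert ops[0].structural_order == ("S", "L", "M")

    def test_ls_pair_is_an_operon(self):
        genes = [gene("c", 100, 2400, "coxL", "l"), gene("c", 2600, 900, "coxS", "s")]
        ops = detect_operons(genes)
        assert len(ops) == 1 and ops[0].structural_order == ("L", "S")

    def test_distant_genes_are_singletons(self):
        genes = [gene("c", 100, 900, "coxS", "s"), gene("c", 6000, 2400, "coxL", "l")]
        ops, singles = detect_operons(genes, include_singletons=True)
        assert ops == [] and len(singles) == 2

    def test_minus_strand_reads_in_transcription_order(self):
        # on the minus strand the rightmost gene is transcribed first
        genes = [
            gene("c", 100, 900, "coxM", "m", "-"),
            gene("c", 1100, 2400, "coxL", "l", "-"),
            gene("c", 3600, 800, "coxS", "s", "-"),
        ]
        assert detect_operons(genes)[0].structural_order == ("S", "L", "M")

    def test_strands_do_not_mix(self):
        genes = [
            gene("c", 100, 900, "coxS", "s", "+"),
            gene("c", 1100, 2400, "coxL", "l", "-"),
        ]
        assert detect_operons(genes) == []

    def test_input_order_irrelevant(self):
        genes = [
            gene("c", 3500, 800, "coxM", "m"),
            gene("c", 100, 900, "coxS", "s"),
            gene("c", 1050, 2400, "coxL", "l"),
        ]
        assert detect_operons(genes)[0].structural_order == ("S", "L", "M")


def slm_operon(coxl_seq, order=("coxS", "coxL", "coxM")):
    genes, proteins, cursor = [], {}, 100
    rng = np.random.default_rng(0)
    for role in order:
        if role == "coxL":
            seq = coxl_seq
        else:
            seq = "".join(rng.choice(list(AA.replace("A", "")), size=200))
        pid = role
        proteins[pid] = seq
        genes.append(gene("c", cursor, 3 * len(seq), role, pid))
        cursor += 3 * len(seq) + 100
    return detect_operons(genes)[0], proteins


class TestClassifyOperon:
    LOOP_II = "M" * 50 + "AYRGAGR" + "W" * 50
    LOOP_I = "M" * 50 + "AYGCSFR" + "W" * 50
    PLAIN = "M" * 50 + "W" * 50

    def test_form_ii_with_accessories(self):
        op, proteins = slm_operon(self.LOOP_II)
        cls = classify_operon(op, proteins, genome_accessories=frozenset("FED"))
        assert cls.form == "form_II"
        assert cls.order_evidence == "S-L-M"
        assert cls.accessory_evidence == frozenset("DEF")

    def test_partial_beats_motif(self):
        """An L-S operon stays partial even with a form II coxL."""
        op, proteins = slm_operon(self.LOOP_II, order=("coxL", "coxS"))
        assert classify_operon(op, proteins).form == "partial"

    def test_form_i(self):
        op, proteins = slm_operon(self.LOOP_I)
        assert classify_operon(op, proteins).form == "putative_form_I"

    def test_motifless_is_unknown(self):
        op, proteins = slm_operon(self.PLAIN)
        assert classify_operon(op, proteins).form == "unknown"

    def test_missing_translation(self):
        op, proteins = slm_operon(self.LOOP_II)
        del proteins["coxL"]
        with pytest.raises(MissingProteinError):
            classify_operon(op, proteins)


class TestFixtureRoundTrip:
    def test_file_roundtrip_matches_in_memory(self, tmp_path):
        """GFF3 + FASTA written to disk classify identically."""
        cfg = synth.SynthConfig(seed=4, n_per_class=2, n_singleton_contigs=1)
        genes, proteins, truth = synth.gen_operon_fixtures(cfg)
        gff, faa = tmp_path / "x.gff3", tmp_path / "x.faa"
        synth.write_gff3(genes, gff)
        synth.write_fasta(proteins, faa)
        table = codh.run_codh(gff, faa)
        in_memory = classify_genome(genes, proteins)
        assert len(table) == len(in_memory)
        by_contig = dict(zip(table["contig"], table["form"]))
        for op, cls in in_memory:
            assert by_contig[op.contig] == cls.form

    def test_generative_labels_recovered(self):
        cfg = synth.SynthConfig(seed=9, n_per_class=3)
        genes, proteins, truth = synth.gen_operon_fixtures(cfg)
        results = classify_genome(genes, proteins)
        assert len(results) == len(truth.operon_labels)
        for op, cls in results:
            assert cls.form == truth.operon_labels[op.contig]

    def test_strand_flip_invariance(self):
        """Mirroring a contig leaves every classification unchanged."""
        cfg = synth.SynthConfig(seed=13, n_per_class=2, n_singleton_contigs=0)
        genes, proteins, truth = synth.gen_operon_fixtures(cfg)
        forms = {
            op.contig: cls.form for op, cls in classify_genome(genes, proteins)
        }
        for contig, form in forms.items():
            if not contig.endswith("_rev"):
                assert forms[contig + "_rev"] == form
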