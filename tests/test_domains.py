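import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rgene_atlas import domains
from rgene_atlas.domains import (
    CANONICAL_LABELS,
    MotifDefinition,
    analyze_protein,
    cc_segments,
    coiled_coil_scan,
    detect_cc_nterm,
    detect_lrr,
    detect_nbs,
    load_motifs,
    parse_consensus,
    scan_protein_motif,
)

MOTIFS = {m.motif_id: m for m in load_motifs()}
AA = "ACDEFGHIKLMNPQRSTVWY"


def brute_force_scan(protein, motif, max_mismatch_fraction):
    """Independent oracle: check every window position by position."""
    L = len(motif.positions)
    budget = int(np.floor(max_mismatch_fraction * L))
    hits = []
    for i in range(len(protein) - L + 1):
        window = protein[i : i + L]
        mism = sum(c not in allowed for c, allowed in zip(window, motif.positions))
        if mism > budget:
            continue
        if motif.core_start >= 0:
            cs, cl = motif.core_start, len(motif.bold_core)
            core_mism = sum(
                c not in allowed
                for c, allowed in zip(window[cs : cs + cl], motif.positions[cs : cs + cl])
            )
            if core_mism > domains.CORE_MAX_MISMATCH:
                continue
        hits.append((i + 1, i + L, (L - mism) / L))
    return hits


class TestMotifScan:
    def test_exact_ploop_core_is_hit(self):
        protein = "MSTART" + "GGLGKTTLA".join(["VRKLNVVSIVGF", "KQVYDKIRAAA"])
        hits = scan_protein_motif(protein, MOTIFS[2])
        assert hits, "P-loop motif with exact GGLGKTTLA core must be detected"

    def test_empty_protein_gives_empty_list(self):
        assert scan_protein_motif("", MOTIFS[2]) == []

    def test_motif_longer_than_protein_gives_empty_list(self):
        assert scan_protein_motif("ACD", MOTIFS[2]) == []

    def test_alternatives_syntax(self):
        motif = MotifDefinition(0, "other", "Q(L/I/V)RD")
        for res in "LIV":
            assert scan_protein_motif(f"AAAQ{res}RDAAA", motif, 0.0)
        assert not scan_protein_motif("AAAQGRDAAA", motif, 0.0)

    @pytest.mark.parametrize("motif_id", [1, 2, 6, 8, 10, 15, 20])
    def test_matches_brute_force_oracle(self, motif_id):
        rng = np.random.default_rng(motif_id)
        motif = MOTIFS[motif_id]
        for _ in range(15):
            protein = "".join(rng.choice(list(AA), size=500))
            # plant one noisy copy so hits actually occur
            inst = list(motif.consensus)
            for _k in range(3):
                inst[rng.integers(len(inst))] = AA[rng.integers(20)]
            pos = rng.integers(0, 400)
            protein = protein[:pos] + "".join(inst) + protein[pos + len(inst) :]
            got = [(h.start, h.end, h.score) for h in scan_protein_motif(protein, motif)]
            assert got == brute_force_scan(protein, motif, 0.4)

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            scan_protein_motif("ACDE", MOTIFS[2], 1.0)


def build_nbs_protein(labels, linker=10, rng=None):
    """Concatenate canonical motif consensi (in the given label order) with
    alanine-free random linkers."""
    rng = rng or np.random.default_rng(0)
    from rgene_atlas.synth import CANONICAL_MOTIF_IDS

    parts = ["M" + "".join(rng.choice(list("GSTQE"), size=linker))]
    for lab in labels:
        parts.append(MOTIFS[CANONICAL_MOTIF_IDS[lab]].consensus)
        parts.append("".join(rng.choice(list("GSTQE"), size=linker)))
    return "".join(parts)


class TestDetectNbs:
    def test_all_eight_planted_in_order(self):
        protein = build_nbs_protein(CANONICAL_LABELS)
        present, labels, span = detect_nbs(protein)
        assert present and labels == set(CANONICAL_LABELS)
        assert span is not None
        # span runs from the first planted motif to the last: roughly the
        # expected ~300-residue NBS region
        assert 200 <= span[1] - span[0] <= 400

    def test_four_motifs_is_below_threshold(self):
        protein = build_nbs_protein(["P-loop", "Kinase-2", "GLPL", "MHDV"])
        present, labels, _ = detect_nbs(protein)
        assert not present
        assert len(labels) == 4

    def test_shuffled_order_is_rejected(self):
        shuffled = ["MHDV", "P-loop", "GLPL", "RNBS-A", "Kinase-2", "RNBS-D", "RNBS-B", "RNBS-C"]
        present, labels, _ = detect_nbs(build_nbs_protein(shuffled))
        assert len(labels) == 8 and not present

    def test_monotone_in_planted_motifs(self):
        """Adding canonical motifs in order never flips present -> absent."""
        order = list(CANONICAL_LABELS)
        was_present = False
        for k in range(5, 9):
            present, _, _ = detect_nbs(build_nbs_protein(order[:k]))
            if was_present:
                assert present
            was_present = was_present or present
        assert was_present


class TestDetectLrr:
    def test_three_planted_repeats(self):
        protein = "GGGG" + "LAALGLSTNGL" * 3 + "GGGG"
        count, spans = detect_lrr(protein)
        assert count == 3 and len(spans) == 3

    def test_single_repeat_is_not_an_lrr_domain(self):
        protein = "GGGG" + "LAALGLSTNGL" + "GGGG"
        count, _ = detect_lrr(protein)
        assert count == 1  # below the two-repeat rule

    def test_poly_alanine_has_no_repeats(self):
        # A is aliphatic but position 9 needs N/T/S/C, so poly-A never matches
        assert detect_lrr("A" * 60) == (0, [])

    def test_region_start_excludes_upstream_matches(self):
        protein = "LAALGLSTNGL" * 2 + "G" * 20
        count, _ = detect_lrr(protein, region_start=23)
        assert count == 0


class TestCoiledCoil:
    def test_strong_heptad_repeat_is_called(self):
        profile = coiled_coil_scan("LEALEGK" * 4)
        assert profile.max() >= 0.9
        assert cc_segments(profile)

    def test_poly_glycine_is_not_called(self):
        assert coiled_coil_scan("G" * 50).max() < 0.1

    def test_too_short_protein_has_empty_profile(self):
        assert len(coiled_coil_scan("LEALEAKLEALEA"[:13])) == 0

    def test_cc_before_nbs_counts_as_nterminal(self):
        protein = "LEALEAK" * 4 + "G" * 30 + "W" * 100
        present, _prob, start = detect_cc_nterm(protein, nbs_span=(60, 160))
        assert present and start is not None and start < 60

    def test_cc_after_nbs_span_is_not_nterminal(self):
        protein = "GSTQEW" * 10 + "LEALEAK" * 6 + "W" * 10
        present, prob, _ = detect_cc_nterm(protein, nbs_span=(5, 50))
        assert prob >= 0.9  # the segment itself is coiled-coil-like
        assert not present  # but it sits after the NBS span

    def test_qlivrd_motif_alone_confers_cc(self):
        protein = "AQVRDA" + "W" * 60
        present, _prob, start = detect_cc_nterm(protein, nbs_span=(20, 60))
        assert present and start == 2


class TestArchitecture:
    @settings(max_examples=10, deadline=None)
    @given(st.integers(0, 10**6))
    def test_random_protein_has_no_architecture(self, seed):
        rng = np.random.default_rng(seed)
        protein = "".join(rng.choice(list(AA), size=300))
        arch = analyze_protein("g", protein)
        assert "NBS" not in arch.domains or len(arch.nbs_motifs_found) >= 5

    def test_planted_architectures_recovered_exactly(self, small_genome):
        gen, _ = small_genome
        for gid, prot in gen.proteins.items():
            arch = analyze_protein(gid, prot)
            assert arch.domains == gen.truth.architectures[gid]


def test_parse_consensus_alternatives():
    assert parse_consensus("Q(L/I/V)RD") == [
        frozenset("Q"),
        frozenset("LIV"),
        frozenset("R"),
        frozenset("D"),
    ]


def test_motif_label_map_is_canonical():
    """The eight canonical labels are carried by the documented motif ids."""
    by_label = {}
    for m in load_motifs():
        by_label.setdefault(m.nbs_label, set()).add(m.motif_id)
    assert by_label["P-loop"] == {2, 9}
    assert by_label["RNBS-A"] == {14}
    assert by_label["Kinase-2"] == {7, 18}
    assert by_label["RNBS-B"] == {10, 20}
    assert by_label["GLPL"] == {3, 15}
    assert by_label["RNBS-C"] == {19}
    assert by_label["RNBS-D"] == {1}
    assert by_label["MHDV"] == {6}
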