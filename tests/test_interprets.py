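"""Interface statistical potentials, permutation nulls, template suitability."""

import numpy as np
import pytest
from scipy import stats

from gcoupler.errors import GcouplerError
from gcoupler.interprets import (
    TemplateComplex,
    extract_contacts,
    permutation_zscore,
    read_potential_tsv,
    score_complex,
    template_suitability,
    write_potential_tsv,
)
from gcoupler.synthetic import generate_toy_complex


@pytest.fixture
def toy():
    return generate_toy_complex(8, seed=12)


class TestScoreComplex:
    def test_zero_potential_scores_zero(self, toy):
        toy.potential = np.zeros((20, 20))
        raw, skipped = score_complex(toy, toy.receptor_chain, toy.galpha_chain)
        assert raw == 0.0 and skipped == 0

    def test_single_contact_reads_table_cell(self):
        from gcoupler.constants import AA_INDEX

        potential = np.zeros((20, 20))
        potential[AA_INDEX["A"], AA_INDEX["G"]] = 1.5
        template = TemplateComplex("t", [(0, 0)], potential, "AW", "GW")
        raw, skipped = score_complex(template, "AW", "GW")
        assert raw == 1.5 and skipped == 0

    def test_unaligned_contact_skipped(self, toy):
        rp, gp = toy.contacts[0]
        partial = {i: i for i in range(len(toy.receptor_chain)) if i != rp}
        template = TemplateComplex(
            "t", [toy.contacts[0]], toy.potential,
            toy.receptor_chain, toy.galpha_chain,
        )
        raw, skipped = score_complex(
            template, toy.receptor_chain, toy.galpha_chain, receptor_map=partial
        )
        assert raw == 0.0 and skipped == 1

    def test_additivity_over_contact_partitions(self, toy):
        half = len(toy.contacts) // 2
        full, _ = score_complex(toy, toy.receptor_chain, toy.galpha_chain)
        parts = 0.0
        for subset in (toy.contacts[:half], toy.contacts[half:]):
            t = TemplateComplex("t", list(subset), toy.potential,
                                toy.receptor_chain, toy.galpha_chain)
            raw, _ = score_complex(t, toy.receptor_chain, toy.galpha_chain)
            parts += raw
        assert full == pytest.approx(parts, abs=1e-12)


class TestPermutationZscore:
    def test_constant_potential_guards_z_and_p(self, toy):
        toy.potential = np.full((20, 20), 2.0)
        out = permutation_zscore(toy, toy.receptor_chain, toy.galpha_chain,
                                 n_perm=50, seed=0)
        assert out.z == 0.0
        assert out.p == 1.0

    def test_best_case_p_is_add_one_formula(self):
        # the wild-type arrangement is uniquely optimal: two contacted
        # positions must carry the chain's single W and single Y at once,
        # which no sampled permutation reproduces -> p = 1/(n_perm+1)
        from gcoupler.constants import AA_INDEX

        potential = np.zeros((20, 20))
        potential[AA_INDEX["W"], AA_INDEX["G"]] = 5.0
        potential[AA_INDEX["Y"], AA_INDEX["G"]] = 3.0
        receptor = "WY" + "A" * 98
        template = TemplateComplex("t", [(0, 0), (1, 0)], potential, receptor, "G")
        out = permutation_zscore(template, receptor, "G", n_perm=100, seed=1)
        assert out.p == pytest.approx(1.0 / 101.0)
        assert out.z > 0

    def test_fixed_seed_reproducible(self, toy):
        a = permutation_zscore(toy, toy.receptor_chain, toy.galpha_chain, seed=9)
        b = permutation_zscore(toy, toy.receptor_chain, toy.galpha_chain, seed=9)
        assert (a.raw, a.z, a.p) == (b.raw, b.z, b.p)

    def test_affine_potential_leaves_z_unchanged(self, toy):
        base = permutation_zscore(toy, toy.receptor_chain, toy.galpha_chain, seed=3)
        toy.potential = 2.5 * toy.potential + 7.0
        scaled = permutation_zscore(toy, toy.receptor_chain, toy.galpha_chain, seed=3)
        assert scaled.z == pytest.approx(base.z, abs=1e-9)

    def test_p_in_unit_interval(self, toy):
        out = permutation_zscore(toy, toy.receptor_chain, toy.galpha_chain, seed=4)
        assert 0.0 < out.p <= 1.0

    def test_null_pvalues_uniform(self):
        """Scoring random sequences against their own null gives uniform p."""
        toy = generate_toy_complex(10, seed=77)
        rng = np.random.default_rng(77)
        from gcoupler.constants import AMINO_ACIDS

        pvals = []
        for k in range(200):
            seq = "".join(AMINO_ACIDS[i]
                          for i in rng.integers(0, 20, len(toy.receptor_chain)))
            out = permutation_zscore(toy, seq, toy.galpha_chain,
                                     n_perm=100, seed=int(rng.integers(2**31)))
            pvals.append(out.p)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestSuitability:
    def test_identical_distributions_unsuitable(self, rng):
        z = list(rng.normal(size=20))
        assert template_suitability(z, list(z)) is False

    def test_separated_distributions_suitable(self, rng):
        zc = rng.normal(2.0, 0.1, 20)
        zu = rng.normal(0.0, 0.1, 20)
        assert template_suitability(zc, zu) is True

    def test_alpha_one_flags_any_difference(self, rng):
        zc = rng.normal(0.0, 1.0, 10)
        zu = rng.normal(0.1, 1.0, 10)
        assert template_suitability(zc, zu, alpha=1.0) is True

    def test_small_group_warns_and_rejects(self):
        with pytest.warns(UserWarning):
            assert template_suitability([1.0, 2.0], [0.0] * 10) is False


PDB_TEMPLATE = """\
CRYST1    1.000    1.000    1.000  90.00  90.00  90.00 P 1           1
{atoms}
END
"""


def _toy_pdb(tmp_path, coords_a, coords_b):
    lines = []
    serial = 1
    for chain, coords in (("A", coords_a), ("B", coords_b)):
        for resi, atoms in enumerate(coords, start=1):
            for name, (x, y, z) in atoms.items():
                lines.append(
                    f"ATOM  {serial:5d}  {name:<3s}GLY {chain}{resi:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           {name[0]}"
                )
                serial += 1
    path = tmp_path / "toy.pdb"
    path.write_text(PDB_TEMPLATE.format(atoms="\n".join(lines)))
    return path


class TestExtractContacts:
    def test_pair_within_cutoff_found(self, tmp_path):
        path = _toy_pdb(
            tmp_path,
            [{"CA": (0.0, 0.0, 0.0)}, {"CA": (20.0, 0.0, 0.0)}],
            [{"CA": (4.9, 0.0, 0.0)}],
        )
        assert extract_contacts(path, "A", "B", cutoff=5.0) == [(0, 0)]

    def test_cutoff_zero_empty(self, tmp_path):
        path = _toy_pdb(
            tmp_path,
            [{"CA": (0.0, 0.0, 0.0)}],
            [{"CA": (1.0, 0.0, 0.0)}],
        )
        assert extract_contacts(path, "A", "B", cutoff=0.0) == []

    def test_matches_brute_force_distance_oracle(self, tmp_path, rng):
        coords_a = [{"CA": tuple(rng.uniform(0, 15, 3)),
                     "CB": tuple(rng.uniform(0, 15, 3))} for _ in range(4)]
        coords_b = [{"CA": tuple(rng.uniform(0, 15, 3))} for _ in range(3)]
        path = _toy_pdb(tmp_path, coords_a, coords_b)
        cutoff = 6.0
        expected = []
        for i, res_a in enumerate(coords_a):
            for j, res_b in enumerate(coords_b):
                if any(
                    np.linalg.norm(np.subtract(p, q)) <= cutoff
                    for p in res_a.values() for q in res_b.values()
                ):
                    expected.append((i, j))
        assert extract_contacts(path, "A", "B", cutoff=cutoff) == expected

    def test_missing_chain_rejected(self, tmp_path):
        path = _toy_pdb(tmp_path, [{"CA": (0, 0, 0)}], [{"CA": (1, 0, 0)}])
        with pytest.raises(GcouplerError):
            extract_contacts(path, "A", "Z")


def test_potential_tsv_roundtrip(tmp_path):
    toy = generate_toy_complex(2, seed=5)
    path = tmp_path / "potential.tsv"
    write_potential_tsv(toy.potential, path)
    assert np.allclose(read_potential_tsv(path), toy.potential)


class TestAlignmentMaps:
    def test_rows_map_skips_gapped_positions(self):
        from gcoupler.interprets import alignment_map_from_rows

        #      query:  A-CD
        #      templ:  AW-D
        mapping = alignment_map_from_rows("A-CD", "AW-D")
        assert mapping == {0: 0, 2: 2}

    def test_fasta_map_roundtrip(self, tmp_path):
        from gcoupler.interprets import alignment_map_from_fasta

        path = tmp_path / "aln.fasta"
        path.write_text(">q\nAC-DE\n>t\nACWD-\n")
        assert alignment_map_from_fasta(path, "q", "t") == {0: 0, 1: 1, 2: 3}

    def test_missing_identifier_rejected(self, tmp_path):
        from gcoupler.interprets import alignment_map_from_fasta

        path = tmp_path / "aln.fasta"
        path.write_text(">q\nAC\n>t\nAC\n")
        with pytest.raises(GcouplerError):
            alignment_map_from_fasta(path, "q", "missing")


def test_permutation_side_is_switchable(toy):
    a = permutation_zscore(toy, toy.receptor_chain, toy.galpha_chain,
                           seed=5, permute_side="receptor")
    b = permutation_zscore(toy, toy.receptor_chain, toy.galpha_chain,
                           seed=5, permute_side="galpha")
    assert a.raw == b.raw  # same observed score, different null
    with pytest.raises(GcouplerError):
        permutation_zscore(toy, toy.receptor_chain, toy.galpha_chain,
                           permute_side="both")
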