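import numpy as np
import pytest

from looplink.exceptions import ContractError
from looplink.sampling import empirical_accumulation, null_accumulation, NullModelConfig
from looplink.synthdata import (
    DetectionModel,
    generate_chain,
    generate_two_state_study,
    observable_pairs,
    perturb_segment,
    sample_replicates,
    synthetic_sequence,
    write_tables,
)
from looplink.structmap import radius_of_gyration
from looplink.xl_io import enumerate_sites, read_xl_table, to_crosslink_set


class TestGenerateChain:
    def test_two_residues_one_bond(self, rng):
        conf = generate_chain(2, 20.0, rng)
        assert conf.L == 2
        assert np.linalg.norm(conf.coords[1] - conf.coords[0]) == pytest.approx(3.8)

    def test_bond_lengths_and_confinement(self, rng):
        conf = generate_chain(150, 25.0, rng)
        bonds = np.linalg.norm(np.diff(conf.coords, axis=0), axis=1)
        assert np.allclose(bonds, 3.8, atol=1e-9)
        assert (np.linalg.norm(conf.coords, axis=1) <= 25.0 + 1e-9).all()

    def test_seeded_determinism(self):
        c1 = generate_chain(50, 30.0, np.random.default_rng(4))
        c2 = generate_chain(50, 30.0, np.random.default_rng(4))
        assert (c1.coords == c2.coords).all()

    def test_tighter_confinement_compacts_the_chain(self):
        rg = {}
        for radius in (20.0, 80.0):
            values = [
                radius_of_gyration(
                    generate_chain(200, radius, np.random.default_rng(s)).coords)
                for s in range(20)
            ]
            rg[radius] = np.mean(values)
        assert rg[20.0] < rg[80.0]

    def test_too_small_sphere_rejected(self, rng):
        with pytest.raises(ContractError):
            generate_chain(5, 1.0, rng)


class TestPerturbSegment:
    def test_empty_segment_is_identity(self, rng):
        conf = generate_chain(30, 20.0, rng)
        assert perturb_segment(conf, (10, 9), rng) is conf

    def test_full_segment_resamples_everything(self, rng):
        conf = generate_chain(30, 20.0, rng)
        new = perturb_segment(conf, (1, 30), rng)
        assert not np.allclose(new.coords, conf.coords)

    def test_bonds_fixed_and_outside_unchanged(self, rng):
        conf = generate_chain(100, 20.0, rng)
        for segment in [(20, 60), (1, 40), (70, 100)]:
            new = perturb_segment(conf, segment, rng)
            bonds = np.linalg.norm(np.diff(new.coords, axis=0), axis=1)
            assert np.allclose(bonds, 3.8, atol=1e-6)
            lo, hi = segment
            outside = [k for k in range(100) if not (lo - 1 <= k <= hi - 1)]
            assert np.array_equal(new.coords[outside], conf.coords[outside])

    def test_invalid_interval_rejected(self, rng):
        conf = generate_chain(30, 20.0, rng)
        with pytest.raises(ContractError):
            perturb_segment(conf, (5, 40), rng)

    def test_longer_segments_rewire_more_contacts(self):
        overlaps = {}
        for length in (20, 80):
            fracs = []
            for s in range(10):
                rng = np.random.default_rng(s)
                conf = generate_chain(150, 20.0, rng)
                sites = enumerate_sites(synthetic_sequence(150, 60, rng))
                base = conf.contact_pairs(sites)
                new = perturb_segment(conf, (30, 30 + length), rng)
                moved = new.contact_pairs(sites)
                if base:
                    fracs.append(len(base & moved) / len(base))
            overlaps[length] = np.mean(fracs)
        assert overlaps[80] < overlaps[20]


class TestObservablePairs:
    def test_probability_profile(self):
        model = DetectionModel(span=30.0, p_max=0.8, decay_scale=5.0)
        assert model.probability(0.0) == 0.8
        assert model.probability(30.0) == 0.8
        assert model.probability(35.0) == pytest.approx(0.8 * np.exp(-1.0))

    def test_zero_decay_cuts_off_at_span(self):
        model = DetectionModel(span=30.0, p_max=1.0, decay_scale=0.0)
        assert model.probability(30.01) == 0.0

    def test_probabilities_non_increasing_in_distance(self, rng):
        conf = generate_chain(60, 20.0, rng)
        sites = enumerate_sites(synthetic_sequence(60, 25, rng))
        probs = observable_pairs(conf, sites, DetectionModel())
        for (i, j), p in probs.items():
            assert j - i >= 2
            d = conf.site_distance(i, j)
            assert p == pytest.approx(DetectionModel().probability(d))


class TestSampleReplicates:
    @pytest.fixture
    def study_parts(self, rng):
        conf = generate_chain(80, 20.0, rng)
        seq = synthetic_sequence(80, 35, rng)
        sites = enumerate_sites(seq)
        probs = observable_pairs(conf, sites, DetectionModel(fp_rate=0.0))
        return sites, probs

    def test_observation_bookkeeping(self, study_parts, rng):
        sites, probs = study_parts
        series = sample_replicates(probs, 4, 25, DetectionModel(fp_rate=0.0),
                                   rng, sites)
        assert series.n_replicates == 4
        assert sum(x.total_observations for _, x in series.replicates) == 100

    def test_no_false_positives_means_all_pairs_observable(self, study_parts, rng):
        sites, probs = study_parts
        series = sample_replicates(probs, 3, 30, DetectionModel(fp_rate=0.0),
                                   rng, sites)
        observable = {p for p, v in probs.items() if v > 0}
        for _, xls in series.replicates:
            assert set(xls.pairs) <= observable

    def test_tables_round_trip_through_parser(self, study_parts, rng, tmp_path):
        sites, probs = study_parts
        series = sample_replicates(probs, 3, 20,
                                   DetectionModel(fp_rate=0.05), rng, sites,
                                   protein_id="synthetic")
        paths = write_tables(series, tmp_path)
        for path, (rep_id, expected) in zip(paths, series.replicates):
            records = read_xl_table(path)
            got = to_crosslink_set(records, "synthetic")
            assert dict(got.pairs) == dict(expected.pairs)
            assert {p: got.provenance[p] for p in got.pairs} == dict(expected.provenance)

    def test_nonuniform_sampling_accumulates_no_faster_than_uniform_null(self):
        # coupon-collector: skewed detection probabilities slow discovery
        rng = np.random.default_rng(11)
        conf = generate_chain(120, 18.0, rng)
        sites = enumerate_sites(synthetic_sequence(120, 60, rng))
        probs = observable_pairs(conf, sites,
                                 DetectionModel(fp_rate=0.0, decay_scale=10.0))
        draws = 40
        series = sample_replicates(probs, 15, draws,
                                   DetectionModel(fp_rate=0.0), rng, sites)
        emp = empirical_accumulation(series, 30, rng)
        pool = sum(1 for v in probs.values() if v > 0)
        # per-replicate unique draws vary; cap the null at the same budget
        per_rep = int(np.mean([len(x.pairs) for _, x in series.replicates]))
        null = null_accumulation(
            NullModelConfig(pool_size=pool, links_per_cycle=per_rep, n_cycles=30),
            15, rng)
        assert np.array(emp.mean_unique)[-1] <= np.array(null.mean_unique)[-1] * 1.05


class TestTwoStateStudy:
    def test_study_shapes_and_determinism(self):
        s1 = generate_two_state_study(np.random.default_rng(2), L=120,
                                      n_sites=40, n_reps=3, draws_per_rep=20,
                                      segment=(40, 90))
        s2 = generate_two_state_study(np.random.default_rng(2), L=120,
                                      n_sites=40, n_reps=3, draws_per_rep=20,
                                      segment=(40, 90))
        assert s1.sequence == s2.sequence
        assert s1.pooled("state_a") == s2.pooled("state_a")
        assert s1.sites.n == 40
        assert s1.pooled("state_b").total_observations == 60

    def test_write_emits_tables_fasta_and_ground_truth(self, tmp_path):
        study = generate_two_state_study(np.random.default_rng(3), L=60,
                                         n_sites=20, n_reps=2, draws_per_rep=10,
                                         segment=(20, 50))
        study.write(tmp_path)
        assert (tmp_path / "synthetic.fasta").exists()
        assert (tmp_path / "ground_truth.json").exists()
        assert len(list((tmp_path / "state_a").glob("*.csv"))) == 2
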