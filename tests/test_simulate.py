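import math

import numpy as np
import pytest

from sxjunction import (
    ReadRecord,
    SimConfig,
    SRegionRef,
    enumerate_breakpoints_with_mh,
    mutate_sequence,
    simulate_dataset,
    simulate_reads,
)
from sxjunction.simulate import SimulationError, hotspot_mask, truth_frame
from sxjunction.junction_call import encode


def _brute_pairs(donor: str, acceptor: str, r: int):
    """Independent enumeration straight from the definition: the r bases
    before the junction match on both references and neither one-base
    extension matches."""
    out = []
    for d in range(r, len(donor) + 1):
        for a in range(r, len(acceptor) + 1):
            if donor[d - r : d] != acceptor[a - r : a]:
                continue
            if d - r - 1 >= 0 and a - r - 1 >= 0 and donor[d - r - 1] == acceptor[a - r - 1]:
                continue
            if d < len(donor) and a < len(acceptor) and donor[d] == acceptor[a]:
                continue
            out.append((d, a))
    return out


class TestEnumerateBreakpoints:
    DONOR = "AAAACCGGTT"
    ACCEPTOR = "CGGTTGGGG"

    @pytest.mark.parametrize("r", range(6))
    def test_matches_brute_force_enumeration(self, r):
        donor = SRegionRef("d", self.DONOR, "donor")
        acceptor = SRegionRef("a", self.ACCEPTOR, "acceptor")
        got = enumerate_breakpoints_with_mh(donor, acceptor, r)
        assert sorted(got) == sorted(_brute_pairs(self.DONOR, self.ACCEPTOR, r))

    def test_shared_cggtt_pair_present(self):
        donor = SRegionRef("d", self.DONOR, "donor")
        acceptor = SRegionRef("a", self.ACCEPTOR, "acceptor")
        assert (10, 5) in enumerate_breakpoints_with_mh(donor, acceptor, 5)

    def test_blunt_pair_present(self):
        donor = SRegionRef("d", "AAAAGG", "donor")
        acceptor = SRegionRef("a", "CCCCTT", "acceptor")
        assert (4, 0) in enumerate_breakpoints_with_mh(donor, acceptor, 0)

    def test_no_common_base_gives_empty(self):
        donor = SRegionRef("d", "AA", "donor")
        acceptor = SRegionRef("a", "GG", "acceptor")
        assert enumerate_breakpoints_with_mh(donor, acceptor, 1) == []

    def test_r_beyond_reference_length_is_error(self):
        donor = SRegionRef("d", "ACGT", "donor")
        acceptor = SRegionRef("a", "ACG", "acceptor")
        with pytest.raises(ValueError):
            enumerate_breakpoints_with_mh(donor, acceptor, 4)


class TestMutateSequence:
    def test_zero_rate_is_identity(self):
        seq = "ACGT" * 25
        out, pos = mutate_sequence(seq, 0.0, 1.0, np.random.default_rng(0))
        assert out == seq and pos == []

    def test_realized_rate_within_binomial_error(self):
        rng = np.random.default_rng(123)
        n, rate = 10_000, 0.03
        seq = "".join(rng.choice(list("ACGT"), size=n))
        _, pos = mutate_sequence(seq, rate, 1.0, np.random.default_rng(42))
        se = math.sqrt(rate * (1 - rate) / n)
        assert abs(len(pos) / n - rate) < 3 * se

    def test_positions_sorted_and_substitutions_differ(self):
        seq = "ACGT" * 50
        out, pos = mutate_sequence(seq, 0.1, 1.0, np.random.default_rng(9))
        assert pos == sorted(pos, key=lambda t: t[0])
        for p, ref, alt in pos:
            assert seq[p] == ref and out[p] == alt and ref != alt

    def test_wrc_gyw_hotspot_mask(self):
        # AGCT: C at index 2 completes a WRC (W=A, R=G) and G at index 1 a
        # GYW (Y=C, W=T); neither terminal base is a hotspot
        mask = hotspot_mask(encode("AGCT"))
        assert mask.tolist() == [False, True, True, False]
        # TGCA: G at 1 is GYW (Y=C, W=A) and C at 2 is WRC (W=T, R=G)
        mask = hotspot_mask(encode("TGCA"))
        assert mask.tolist() == [False, True, True, False]
        # GCT alone has no hotspot: the G lacks a W at +2 (T is W — check a
        # true negative instead): in "GGGG" nothing qualifies
        assert hotspot_mask(encode("GGGG")).tolist() == [False] * 4

    def test_hotspot_multiplier_raises_realized_rate(self):
        seq = "AGC" * 4000  # every third base is a WRC hotspot
        _, base_pos = mutate_sequence(seq, 0.02, 1.0, np.random.default_rng(5))
        _, hot_pos = mutate_sequence(seq, 0.02, 5.0, np.random.default_rng(5))
        assert len(hot_pos) > len(base_pos)


class TestSimulateReads:
    def test_determinism_byte_identical(self, switch_refs, tmp_path):
        donor, acceptor = switch_refs
        cfg = SimConfig(n_reads=40, seed=31, mutation_rate=0.01, seq_error_rate=0.002)
        p1 = simulate_dataset(cfg, donor, acceptor, tmp_path / "a")
        p2 = simulate_dataset(cfg, donor, acceptor, tmp_path / "b")
        assert p1[0].read_bytes() == p2[0].read_bytes()
        assert p1[1].read_bytes() == p2[1].read_bytes()

    def test_point_mass_blunt_config(self, switch_refs):
        donor, acceptor = switch_refs
        cfg = SimConfig(n_reads=50, mh_distribution={0: 1.0}, mutation_rate=0.0, seed=3)
        reads, truths, _ = simulate_reads(cfg, donor, acceptor)
        assert len(reads) == 50
        assert all(t.mh_len == 0 and not t.insertion_seq for t in truths)

    def test_empty_dataset_has_valid_headers(self, switch_refs, tmp_path):
        donor, acceptor = switch_refs
        cfg = SimConfig(n_reads=0, seed=1)
        reads_path, truth_path = simulate_dataset(cfg, donor, acceptor, tmp_path / "empty")
        assert reads_path.read_text() == ""
        header = truth_path.read_text().splitlines()[0].split("\t")
        assert header[:4] == ["read_id", "donor_break", "acceptor_break", "mh_len"]

    def test_truth_reassembly_reproduces_reads(self, switch_refs):
        donor, acceptor = switch_refs
        cfg = SimConfig(n_reads=60, mutation_rate=0.02, seq_error_rate=0.005, seed=77)
        reads, truths, _ = simulate_reads(cfg, donor, acceptor)
        for read, t in zip(reads, truths):
            h_d = (cfg.read_length - len(t.insertion_seq)) // 2
            s = t.donor_break - h_d
            core = (
                donor.sequence[s : t.donor_break]
                + t.insertion_seq
                + acceptor.sequence[t.acceptor_break :]
            )[: cfg.read_length]
            rebuilt = list(core)
            for p, ref, alt in t.mutation_positions + t.error_positions:
                assert rebuilt[p] == ref
                rebuilt[p] = alt
            assert "".join(rebuilt) == read.sequence

    def test_realized_mh_is_maximal(self, mixed_dataset, switch_refs):
        """Brute-force check of the maximality contract: the error-free read's
        junction matches both germlines for exactly mh_len bases."""
        donor, acceptor = switch_refs
        reads, truths, _ = mixed_dataset
        for read, t in zip(reads, truths):
            d, a, r = t.donor_break, t.acceptor_break, t.mh_len
            assert donor.sequence[d - r : d] == acceptor.sequence[a - r : a]
            if not t.insertion_seq:
                if d - r - 1 >= 0 and a - r - 1 >= 0:
                    assert donor.sequence[d - r - 1] != acceptor.sequence[a - r - 1]
                if d < len(donor) and a < len(acceptor):
                    assert donor.sequence[d] != acceptor.sequence[a]

    def test_mh_distribution_recovered(self, switch_refs):
        donor, acceptor = switch_refs
        cfg = SimConfig(
            n_reads=600,
            mh_distribution={r: 1 / 12 for r in range(2, 14)},
            mutation_rate=0.0,
            seed=8,
        )
        _, truths, _ = simulate_reads(cfg, donor, acceptor)
        vals = np.array([t.mh_len for t in truths])
        se = vals.std(ddof=1) / math.sqrt(len(vals))
        assert abs(vals.mean() - 7.5) < 3 * se

    def test_unrealizable_requests_raise(self):
        rng = np.random.default_rng(0)
        donor = SRegionRef("d", "".join(rng.choice(list("ACGT"), size=120)), "donor")
        acceptor = SRegionRef("a", "".join(rng.choice(list("ACGT"), size=120)), "acceptor")
        cfg = SimConfig(n_reads=5, read_length=60, mh_distribution={13: 1.0}, seed=2)
        with pytest.raises(SimulationError):
            simulate_reads(cfg, donor, acceptor)

    def test_intra_deletion_mode_respects_min_deletion(self, switch_refs):
        donor, _ = switch_refs
        cfg = SimConfig(
            n_reads=30,
            intra_deletion_mode=True,
            min_deletion=25,
            mutation_rate=0.0,
            mh_distribution={r: 0.25 for r in range(4)},
            seed=4,
        )
        _, truths, _ = simulate_reads(cfg, donor, donor)
        assert all(t.acceptor_break - t.donor_break >= 25 for t in truths)


class TestSimConfigValidation:
    def test_probabilities_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SimConfig(mh_distribution={0: 0.5, 1: 0.4})

    def test_rates_bounded(self):
        with pytest.raises(ValueError):
            SimConfig(mutation_rate=0.5)

    def test_truth_frame_columns(self, switch_refs):
        donor, acceptor = switch_refs
        cfg = SimConfig(n_reads=3, seed=1)
        _, truths, _ = simulate_reads(cfg, donor, acceptor)
        df = truth_frame(truths)
        assert list(df.columns) == [
            "read_id", "donor_break", "acceptor_break", "mh_len",
            "insertion_seq", "n_mutations", "mutation_positions", "n_errors",
        ]
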