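"""Generator contracts: determinism, truth consistency, count laws, packing."""
import numpy as np
import pandas as pd
import pytest

from mitoquant import simulate as sim
from tests.conftest import SMALL


def test_identical_config_gives_bit_identical_fields(small_nf):
    cfg, fld, truth = small_nf
    fld2, truth2 = sim.generate_field(cfg)
    for role in fld.channels:
        assert np.array_equal(fld.channels[role], fld2.channels[role])
    for kind in truth.masks:
        assert np.array_equal(truth.masks[kind].labels, truth2.masks[kind].labels)
    pd.testing.assert_frame_equal(truth.per_cell, truth2.per_cell)


def test_truth_counts_match_label_images(small_nf):
    """per_cell counts must tally exactly with the emitted label maps."""
    _, _, truth = small_nf
    mito = truth.masks["mito"].labels
    cells = truth.masks["cells"].labels
    tallies = {int(c): {"yellow": 0, "red_only": 0} for c in truth.per_cell.cell_id}
    for oid, cls in truth.object_class.items():
        host = int(np.bincount(cells[mito == oid]).argmax())
        assert host > 0, "every truth object lies inside a cell"
        tallies[host][cls] += 1
    for row in truth.per_cell.itertuples():
        assert tallies[row.cell_id]["red_only"] == row.n_red_only
        assert tallies[row.cell_id]["yellow"] == row.n_yellow


@pytest.mark.parametrize(
    "rate,mult", [(0.0, 1.0), (5.0, 0.0)], ids=["rate-zero", "multiplier-zero"]
)
def test_no_acidified_puncta_when_rate_vanishes(rate, mult):
    cfg = sim.SimulationConfig(**SMALL, acidified_rate=rate, seed=1)
    _, truth = sim.generate_field(cfg, sim.TreatmentEffect("x", acidified_multiplier=mult))
    assert truth.per_cell.n_red_only.eq(0).all()
    assert "red_only" not in set(truth.object_class.values())


def test_acidified_counts_follow_poisson_law():
    """Empirical mean over 225 cells within 3 standard errors of lambda = 3."""
    cfg = sim.SimulationConfig(field_shape=(680, 680), n_cells=225,
                               acidified_rate=3.0, seed=5)
    _, truth = sim.generate_field(cfg)
    mean = truth.per_cell.n_red_only.mean()
    se = np.sqrt(3.0 / 225)
    assert abs(mean - 3.0) <= 3 * se


def test_noise_free_blur_free_fields_have_zero_background(small_nf):
    cfg, _, _ = small_nf
    fld, truth = sim.generate_field(cfg.replace(psf_sigma_px=0.0))
    cells = truth.masks["cells"].labels > 0
    nuclei = truth.masks["nuclei"].labels > 0
    assert not fld.channels["mcherry"][~cells].any()
    assert not fld.channels["egfp"][~cells].any()
    assert not fld.channels["nuclei"][~nuclei].any()


def test_lysosomal_block_reverts_to_basal_rate():
    """Under a lysosomal block the red-only count keeps the basal law and the
    induced excess appears as dual-channel puncta instead."""
    cfg = sim.SimulationConfig(field_shape=(680, 680), n_cells=225,
                               acidified_rate=1.0, seed=9)
    blocked = sim.TreatmentEffect("dfp+baf", acidified_multiplier=3.0, lysosomal_block=True)
    _, truth = sim.generate_field(cfg, blocked)
    mean = truth.per_cell.n_red_only.mean()
    assert abs(mean - 1.0) <= 3 * np.sqrt(1.0 / 225)
    # blocked excess rendered as extra yellow puncta: more yellow objects than
    # an untreated field of the same geometry
    _, untreated = sim.generate_field(cfg)
    assert truth.per_cell.n_yellow.sum() > untreated.per_cell.n_yellow.sum()


class TestDoseSeries:
    def test_single_effect_equals_generate_field(self, small_nf):
        cfg, fld, _ = small_nf
        (fld2, _), = sim.generate_dose_series(cfg, [sim.CONTROL])
        for role in fld.channels:
            assert np.array_equal(fld.channels[role], fld2.channels[role])

    def test_truth_means_non_increasing_for_decreasing_multipliers(self):
        cfg = sim.SimulationConfig(field_shape=(340, 340), n_cells=49,
                                   acidified_rate=4.0, seed=2)
        effects = [
            sim.TreatmentEffect(f"d{i}", acidified_multiplier=m, dose=float(i))
            for i, m in enumerate([1.0, 0.5, 0.0])
        ]
        series = sim.generate_dose_series(cfg, effects)
        means = [t.per_cell.n_red_only.mean() for _, t in series]
        assert all(a >= b for a, b in zip(means, means[1:]))

    def test_empty_effect_list_rejected(self, small_nf):
        with pytest.raises(ValueError, match="empty"):
            sim.generate_dose_series(small_nf[0], [])

    def test_unordered_doses_rejected(self, small_nf):
        effects = [sim.TreatmentEffect("hi", dose=10.0), sim.TreatmentEffect("lo", dose=1.0)]
        with pytest.raises(ValueError, match="ordered"):
            sim.generate_dose_series(small_nf[0], effects)


class TestPacking:
    def test_too_many_cells_raises(self):
        with pytest.raises(sim.PackingError):
            sim.SimulationConfig(field_shape=(120, 120), n_cells=50)

    def test_slot_shortage_raises(self):
        cfg = sim.SimulationConfig(field_shape=(300, 300), n_cells=120,
                                   cell_radius_px=(10.0, 1.0))
        with pytest.raises(sim.PackingError, match="slots"):
            sim.generate_field(cfg)

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            sim.SimulationConfig(lc3_mito_overlap_fraction=1.2)
        with pytest.raises(ValueError):
            sim.SimulationConfig(acidified_rate=-1.0)


class TestTissue:
    def test_zero_p62_rate_gives_zero_area(self):
        cfg = sim.TissueConfig(p62_puncta_per_mn=0.0, seed=3)
        _, truth = sim.generate_tissue_section(cfg)
        assert truth.tissue_truth.p62_area_px.eq(0).all()

    def test_full_tomm20_fill_covers_whole_soma(self):
        cfg = sim.TissueConfig(tomm20_fill_fraction=1.0, seed=3,
                               noise_model=sim.NOISE_FREE, psf_sigma_px=0.0)
        _, truth = sim.generate_tissue_section(cfg)
        tt = truth.tissue_truth
        assert (tt.tomm20_area_px == tt.mn_area_px).all()

    def test_mn_count_below_one_rejected(self):
        with pytest.raises(ValueError):
            sim.TissueConfig(n_mn=0)

    def test_p62_halving_effect_scales_truth_mean(self):
        cfg = sim.TissueConfig(n_mn=12, seed=0)
        ctl = [
            sim.generate_tissue_section(cfg.replace(seed=s))[1].tissue_truth.p62_area_px.mean()
            for s in range(6)
        ]
        half = [
            sim.generate_tissue_section(
                cfg.replace(seed=100 + s), sim.TissueEffect("tg", p62_multiplier=0.5)
            )[1].tissue_truth.p62_area_px.mean()
            for s in range(6)
        ]
        ratio = np.mean(half) / np.mean(ctl)
        assert 0.35 < ratio < 0.65

    def test_cohort_is_deterministic_and_labelled(self):
        groups = {"WT": sim.TissueEffect("WT"), "TG": sim.TissueEffect("TG", p62_multiplier=0.6)}
        cfg = sim.TissueConfig(n_mn=10, seed=0)
        a = sim.generate_tissue_cohort(cfg, groups, n_animals_per_group=2,
                                       stacks_per_animal=2, base_seed=4)
        b = sim.generate_tissue_cohort(cfg, groups, n_animals_per_group=2,
                                       stacks_per_animal=2, base_seed=4)
        assert len(a) == 8
        assert {r["group"] for r in a} == {"WT", "TG"}
        for ra, rb in zip(a, b):
            pd.testing.assert_frame_equal(ra["truth"].tissue_truth, rb["truth"].tissue_truth)
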