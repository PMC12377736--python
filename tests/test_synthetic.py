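import numpy as np
import pytest

from els_mapper.synthetic import (
    CohortDesign,
    GroupDesign,
    SceneSpec,
    StructureSpec,
    generate_cohort_counts,
    generate_ground_truth,
    generate_scene,
    random_scene_spec,
)


def type3_spec(center=(500.0, 500.0), nb=30, nt=40, ki67=0.2):
    return StructureSpec(
        center=center, target_type=3, n_b_cells=nb, n_t_cells=nt,
        ki67_fraction=ki67, radius=60.0, layout="core-shell",
    )


class TestStructureSpec:
    def test_type_layout_consistency_enforced(self):
        with pytest.raises(ValueError):
            StructureSpec(center=(0, 0), target_type=3, n_b_cells=10, n_t_cells=10,
                          ki67_fraction=0.0, layout="core-shell")  # type 3 needs ki67
        with pytest.raises(ValueError):
            StructureSpec(center=(0, 0), target_type=2, n_b_cells=10, n_t_cells=10,
                          ki67_fraction=0.5, layout="adjacent-compartments")
        with pytest.raises(ValueError):
            StructureSpec(center=(0, 0), target_type=1, n_b_cells=10, n_t_cells=10,
                          layout="core-shell")
        with pytest.raises(ValueError):
            StructureSpec(center=(0, 0), target_type=1, n_b_cells=10, n_t_cells=10,
                          layout="single-lineage")

    def test_scene_rejects_center_outside_canvas(self):
        with pytest.raises(ValueError, match="outside canvas"):
            SceneSpec(canvas_size=(256, 256), pixel_size=2.0,
                      structures=(type3_spec(center=(2000.0, 100.0)),))

    def test_scene_rejects_overlapping_structures(self):
        a = type3_spec(center=(300.0, 300.0))
        b = type3_spec(center=(350.0, 300.0))
        with pytest.raises(ValueError, match="closer than"):
            SceneSpec(canvas_size=(512, 512), structures=(a, b))
        SceneSpec(canvas_size=(512, 512), structures=(a, b), allow_overlap=True)


class TestGenerateScene:
    def test_empty_scene_is_all_zeros(self):
        spec = SceneSpec(canvas_size=(64, 64), background_noise=0.0, seed=7)
        image, gt = generate_scene(spec)
        assert all(np.all(ch == 0) for ch in image.channels.values())
        assert len(gt.cells) == 0 and len(gt.structures) == 0

    def test_seed_determinism_bit_identical(self):
        spec = SceneSpec(canvas_size=(256, 256), structures=(type3_spec(),),
                         background_noise=0.3, seed=11)
        im1, gt1 = generate_scene(spec)
        im2, gt2 = generate_scene(spec)
        for ch in im1.channels:
            assert np.array_equal(im1.channels[ch], im2.channels[ch])
        assert gt1.cells.equals(gt2.cells)

    def test_type3_ground_truth_counts(self):
        # 30 B core + 40 T shell at ki67 0.2 -> 70 cells, 6 Ki67+, 1 structure
        spec = SceneSpec(canvas_size=(512, 512), structures=(type3_spec(),), seed=1)
        gt = generate_ground_truth(spec)
        assert len(gt.cells) == 70
        assert int(gt.cells.ki67.sum()) == 6
        assert len(gt.structures) == 1
        assert set(gt.cells[gt.cells.ki67].lineage) == {"B"}

    def test_cell_count_conservation(self):
        specs = tuple(
            type3_spec(center=(300.0 + 400 * i, 300.0), nb=10 + i, nt=20 + i, ki67=0.3)
            for i in range(3)
        )
        scene = SceneSpec(canvas_size=(1024, 1024), structures=specs, seed=5)
        gt = generate_ground_truth(scene)
        assert len(gt.cells) == sum(s.n_cells for s in specs)
        # every cell's parent structure exists
        assert set(gt.cells.structure_id) <= set(gt.structures.structure_id)

    def test_channel_fidelity_noise_free(self):
        """Ki67+ cells leave signal in lineage and Ki67 channels; Ki67- cells none."""
        spec = SceneSpec(canvas_size=(512, 512), structures=(type3_spec(),),
                         background_noise=0.0, seed=3)
        image, gt = generate_scene(spec)
        px = spec.pixel_size
        ki = image.channels["Ki67"]
        for row in gt.cells.itertuples(index=False):
            i, j = int(round(row.y_um / px)), int(round(row.x_um / px))
            assert image.channels[row.lineage][i, j] > 0.5
            if row.ki67:
                assert ki[i, j] > 0.5
        # Ki67- only positions: far from any Ki67+ cell the channel is exactly 0
        assert np.all(ki[ki > 0] >= 0)
        assert (ki > 0).sum() < ki.size  # sparse signal
        neg = gt.cells[~gt.cells.ki67]
        pos = gt.cells[gt.cells.ki67][["x_um", "y_um"]].to_numpy()
        for row in neg.itertuples(index=False):
            if len(pos) and np.min(np.hypot(*(pos - (row.x_um, row.y_um)).T)) < 30:
                continue  # bleed-over from a nearby Ki67+ punctum
            i, j = int(round(row.y_um / px)), int(round(row.x_um / px))
            assert ki[i, j] < 1e-4

    def test_landmarks_scaled_to_scene(self, template):
        spec = SceneSpec(canvas_size=(256, 256), pixel_size=2.0, template=template, seed=0)
        gt = generate_ground_truth(spec)
        assert set(gt.landmarks) == set(template.landmarks)
        for name, (x, y) in gt.landmarks.items():
            u, v = template.landmarks[name]
            assert np.isclose(x, u * 512) and np.isclose(y, v * 512)

    def test_random_scene_spec_structures_valid(self, template):
        spec = random_scene_spec(seed=42, template=template)
        assert 8 <= len(spec.structures) <= 12
        gt = generate_ground_truth(spec)
        assert (gt.structures.els_type.isin([1, 2, 3])).all()


def flat_design(mean=10.0, dispersion=0.0, n_mice=5, model="negative-binomial"):
    g = GroupDesign(genotype="WT", sex="M", age_group="12", n_mice=n_mice,
                    mean_count=mean, dispersion=dispersion)
    return CohortDesign(groups=(g,), count_model=model, seed=99)


class TestCohort:
    def test_zero_dispersion_counts_are_deterministic(self):
        table = generate_cohort_counts(flat_design(mean=10.75, dispersion=0.0))
        assert (table.mice.total_count == 11).all()  # round(10.75)

    @pytest.mark.parametrize("model", ["negative-binomial", "lognormal-rounded"])
    def test_sample_mean_matches_design(self, model):
        # mean 10, dispersion 5 -> variance 10 + 5*100 = 510 for the NB model
        table = generate_cohort_counts(
            flat_design(mean=10.0, dispersion=5.0, n_mice=10_000, model=model)
        )
        counts = table.mice.total_count.to_numpy(float)
        se = counts.std(ddof=1) / np.sqrt(len(counts))
        assert abs(counts.mean() - 10.0) < 3 * se + 1e-9

    def test_nb_variance_matches_parameterization(self):
        table = generate_cohort_counts(flat_design(mean=10.0, dispersion=0.5, n_mice=20_000))
        var = table.mice.total_count.to_numpy(float).var(ddof=1)
        assert abs(var - (10 + 0.5 * 100)) / (10 + 0.5 * 100) < 0.1

    def test_seed_determinism(self):
        d = flat_design(mean=8.0, dispersion=0.3, n_mice=20)
        t1, t2 = generate_cohort_counts(d), generate_cohort_counts(d)
        assert t1.mice.equals(t2.mice) and t1.sizes.equals(t2.sizes)

    def test_summary_consistency(self):
        table = generate_cohort_counts(flat_design(mean=12, dispersion=0.4, n_mice=30))
        m = table.mice
        assert (m.n_type1 + m.n_type2 + m.n_type3 == m.total_count).all()
        per_mouse = table.sizes.groupby("mouse_id").size()
        nonzero = m[m.total_count > 0].set_index("mouse_id")
        assert (per_mouse.reindex(nonzero.index) == nonzero.total_count).all()

    def test_invalid_designs_rejected(self):
        with pytest.raises(ValueError):
            GroupDesign(genotype="WT", sex="M", age_group="1", n_mice=0, mean_count=5,
                        dispersion=0.1)
        with pytest.raises(ValueError):
            GroupDesign(genotype="WT", sex="M", age_group="1", n_mice=5, mean_count=-1,
                        dispersion=0.1)
        with pytest.raises(ValueError):
            GroupDesign(genotype="WT", sex="M", age_group="1", n_mice=5, mean_count=5,
                        dispersion=0.1, type_mix=(0.5, 0.5, 0.5))
        with pytest.raises(ValueError):
            flat_design(model="poisson")
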