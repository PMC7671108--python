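"""The synthetic-data generator: determinism, geometry, recoverability."""
import numpy as np
import pytest

from skatemorph import (
    SyntheticSpec,
    gpa,
    maturity_breakpoint,
    procrustes_distance,
    read_metadata,
    read_newick,
    read_sliders,
    read_tps,
    simulate_clasper_growth,
    simulate_interspecific,
    simulate_ontogeny,
    simulate_skeletal_traits,
    template_outline,
)
from skatemorph.synthetic import (
    ClasperGrowthSpec,
    OntogenySpec,
    _self_intersects,
    dimorphism_field,
    ontogeny_field,
)


class TestTemplateOutline:
    def test_deterministic(self):
        a = template_outline(35).coords
        b = template_outline(35).coords
        np.testing.assert_array_equal(a, b)

    def test_equal_arc_length_spacing(self):
        # chords of equal-arc segments differ only through curvature
        # (relative (kappa*s)^2/24 effect, ~1e-4 here)
        coords = template_outline(40).coords
        seglen = np.linalg.norm(np.diff(coords, axis=0), axis=1)
        assert seglen.std() / seglen.mean() < 1e-3

    def test_not_self_intersecting(self):
        assert not _self_intersects(template_outline(35).coords)
        # sanity: the oracle does detect a crossing polyline
        bow_tie = np.array([(0, 0), (1, 1), (1, 0), (0, 1)], dtype=float)
        assert _self_intersects(bow_tie)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            template_outline(7)


class TestDeformationFields:
    def test_fields_are_unit_and_orthogonal(self, template35):
        u = dimorphism_field(template35)
        v = ontogeny_field(template35)
        assert np.linalg.norm(u) == pytest.approx(1.0, abs=1e-12)
        assert np.linalg.norm(v) == pytest.approx(1.0, abs=1e-12)
        assert abs(u @ v) < 1e-9

    def test_fields_survive_superimposition(self, template35):
        """Adding the field must change shape, not position/size/rotation:
        the recovered Procrustes distance tracks the applied magnitude."""
        u = dimorphism_field(template35).reshape(-1, 2)
        base = template35.coords
        for d in (0.01, 0.03):
            aligned = gpa([base, base + d * u])
            got = procrustes_distance(aligned.shapes[0], aligned.shapes[1])
            assert got == pytest.approx(d, rel=0.02)


class TestReproducibility:
    def test_identical_spec_and_seed_give_identical_files(self, tmp_path):
        spec = SyntheticSpec(seed=5, n_species=6)
        a, b = tmp_path / "a", tmp_path / "b"
        simulate_interspecific(spec, a)
        simulate_interspecific(spec, b)
        for name in ("interspecific.tps", "sliders.txt", "metadata.csv", "tree.nwk", "truth.txt"):
            assert (a / name).read_bytes() == (b / name).read_bytes()
        spec_o = SyntheticSpec(seed=5)
        simulate_ontogeny(spec_o, a / "ont")
        simulate_ontogeny(spec_o, b / "ont")
        for name in ("ontogeny.tps", "metadata.csv", "skeletal.csv", "truth.txt"):
            assert (a / "ont" / name).read_bytes() == (b / "ont" / name).read_bytes()

    def test_outputs_parse_cleanly(self, tmp_path):
        spec = SyntheticSpec(seed=8, n_species=6)
        simulate_interspecific(spec, tmp_path)
        configs = read_tps(tmp_path / "interspecific.tps")
        assert len(configs) == 12
        sliders = read_sliders(tmp_path / "sliders.txt", k=configs[0].k)
        assert sliders.n_sliders == 33
        records = read_metadata(tmp_path / "metadata.csv")
        assert len(records) == 12
        tree = read_newick(tmp_path / "tree.nwk")
        assert tree.n_leaves == 6
        assert {r.species for r in records} == set(tree.leaf_labels)

    def test_truth_manifest_holds_ground_truth(self, tmp_path):
        spec = SyntheticSpec(seed=8, n_species=4, dimorphism_magnitudes=(0.02, 0.04, 0.06, 0.08))
        dataset = simulate_interspecific(spec, tmp_path)
        text = (tmp_path / "truth.txt").read_text()
        for name, value in dataset.truth.items():
            assert f"{name}={value}" in text


class TestInterspecificRecovery:
    def test_null_magnitudes_stay_at_noise_floor(self):
        spec = SyntheticSpec(
            seed=9, n_species=6, dimorphism_magnitudes=(0.0,) * 6
        )
        dataset = simulate_interspecific(spec)
        aligned = gpa(
            sorted(dataset.configs, key=lambda c: c.specimen_id),
            sliders=dataset.sliders,
        )
        index = {sid: i for i, sid in enumerate(aligned.specimen_ids)}
        noise_floor = spec.digitizing_noise_sd * np.sqrt(2 * 2 * spec.n_landmarks)
        for sp in sorted({r.species for r in dataset.records}):
            length = procrustes_distance(
                aligned.shapes[index[f"{sp}_F"]], aligned.shapes[index[f"{sp}_M"]]
            )
            assert length <= 3 * noise_floor

    def test_exact_construction_recovers_magnitude(self):
        """No noise, no dispersion, no species spread: estimated lengths
        match the generating magnitude to the GPA nonlinearity tolerance."""
        d = 0.04
        spec = SyntheticSpec(
            seed=3,
            n_species=8,
            bm_rate=0.0,
            digitizing_noise_sd=0.0,
            angular_dispersion_deg=0.0,
            dimorphism_magnitudes=(d,) * 8,
        )
        dataset = simulate_interspecific(spec)
        aligned = gpa(
            sorted(dataset.configs, key=lambda c: c.specimen_id),
            sliders=dataset.sliders,
        )
        index = {sid: i for i, sid in enumerate(aligned.specimen_ids)}
        for sp in sorted({r.species for r in dataset.records}):
            length = procrustes_distance(
                aligned.shapes[index[f"{sp}_F"]], aligned.shapes[index[f"{sp}_M"]]
            )
            assert length == pytest.approx(d, rel=0.02)


class TestOntogeny:
    def test_zero_noise_immature_sexes_identical_at_equal_dw(self):
        spec = SyntheticSpec(seed=4, digitizing_noise_sd=0.0)
        dataset = simulate_ontogeny(spec)
        by_id = {c.specimen_id: c for c in dataset.configs}
        recs = {r.specimen_id: r for r in dataset.records}
        male = next(
            r for r in dataset.records if r.sex == "male" and r.maturity == "immature"
        )
        # rebuild a female at exactly the male's disc width via the model:
        # immature shapes contain only the shared allometric trend, so the
        # unit-size shapes must coincide
        female = next(
            r for r in dataset.records if r.sex == "female" and r.maturity == "immature"
        )
        male_shape = by_id[male.specimen_id].coords / male.disc_width
        female_shape = by_id[female.specimen_id].coords / female.disc_width
        # same DW would give identical shapes; different DW differ only by
        # the allometric term, bounded by the allometry scale
        assert (
            procrustes_distance(male_shape, female_shape)
            <= spec.ontogeny.allometry_scale + 1e-9
        )

    def test_maturity_column_matches_threshold_rule(self):
        dataset = simulate_ontogeny(SyntheticSpec(seed=6))
        bp = float(dataset.truth["breakpoint"])
        for rec in dataset.records:
            expected = "mature" if rec.disc_width > bp else "immature"
            assert rec.maturity == expected
        # both sides populated for each sex
        for sex in ("male", "female"):
            stages = {r.maturity for r in dataset.records if r.sex == sex}
            assert stages == {"immature", "mature"}

    def test_sample_sizes_match_design(self):
        dataset = simulate_ontogeny(SyntheticSpec(seed=6))
        males = [r for r in dataset.records if r.sex == "male"]
        females = [r for r in dataset.records if r.sex == "female"]
        assert (len(males), len(females)) == (21, 22)
        assert all(r.clasper_length is not None for r in males)
        assert all(r.clasper_length is None for r in females)
        lo, hi = 50.6, 109.5
        assert all(lo <= r.disc_width <= hi for r in dataset.records)


class TestOntogenyTrajectoryRecovery:
    def test_threefold_maturation_ratio_recovered(self):
        """With the male maturation effect three times the female one, the
        estimated male/female ontogenetic trajectory ratio lands within 20%
        of 3 at ~20 specimens per sex-by-stage cell (median of 3 series)."""
        from skatemorph import permutation_test

        ratios = []
        for seed in (301, 302, 303):
            spec = SyntheticSpec(
                seed=seed, ontogeny=OntogenySpec(n_males=40, n_females=40)
            )
            dataset = simulate_ontogeny(spec)
            aligned = gpa(
                sorted(dataset.configs, key=lambda c: c.specimen_id),
                sliders=dataset.sliders,
            )
            recs = {r.specimen_id: r for r in dataset.records}
            sexes = np.array([recs[s].sex for s in aligned.specimen_ids])
            stages = np.array([recs[s].maturity for s in aligned.specimen_ids])
            res = permutation_test(
                aligned.flattened(), sexes, stages, n_perm=199, seed=1
            )
            l_female, l_male = res.L_per_group
            ratios.append(l_male / l_female)
        assert np.median(ratios) == pytest.approx(3.0, rel=0.2)


class TestClasperGrowth:
    def test_noiseless_growth_recovered_by_breakpoint_fit(self):
        spec = SyntheticSpec(
            seed=2, clasper_growth=ClasperGrowthSpec(noise_sd=0.0)
        )
        dw, cl = simulate_clasper_growth(spec)
        res = maturity_breakpoint(dw, cl)
        # breakpoint falls in the grid cell containing the true hinge
        neighbors = np.sort(dw)
        gap = neighbors[np.searchsorted(neighbors, 84.0)] - neighbors[
            np.searchsorted(neighbors, 84.0) - 1
        ]
        assert abs(res.breakpoint_dw - 84.0) <= gap

    def test_degenerate_hinge_equals_straight_line(self):
        spec = SyntheticSpec(
            seed=2,
            clasper_growth=ClasperGrowthSpec(
                slope_below=0.4, slope_above=0.4, noise_sd=0.0
            ),
        )
        dw, cl = simulate_clasper_growth(spec)
        res = maturity_breakpoint(dw, cl)
        design = np.column_stack([np.ones(dw.size), dw])
        beta, *_ = np.linalg.lstsq(design, cl, rcond=None)
        line_sse = ((cl - design @ beta) ** 2).sum()
        assert res.sse == pytest.approx(line_sse, abs=1e-9 + 1e-9 * line_sse)


class TestSkeletalTraits:
    def test_values_strictly_positive_and_complete(self):
        frame = simulate_skeletal_traits(SyntheticSpec(seed=3))
        trait_cols = [
            c for c in frame.columns if c not in ("specimen_id", "sex", "disc_width_mm")
        ]
        assert len(trait_cols) == 9
        assert (frame[trait_cols] > 0).all().all()
        assert len(frame) == 43

    def test_dimorphic_structure_of_defaults(self):
        spec = SyntheticSpec(seed=3)
        slope_dimorphic = [
            t.name for t in spec.skeletal if t.slope_f != t.slope_m
        ]
        intercept_dimorphic = [
            t.name
            for t in spec.skeletal
            if t.slope_f == t.slope_m and t.intercept_f != t.intercept_m
        ]
        assert len(slope_dimorphic) == 3
        assert len(intercept_dimorphic) == 2
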