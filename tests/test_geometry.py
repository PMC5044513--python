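import numpy as np
import pytest

from perfusim.geometry import (
    FB_WIDTHS,
    InvalidGeometryError,
    build_fluidizedbed,
    build_geometry,
    build_quasivivo,
    build_realbio,
    generate_mesh,
    kozeny_permeability,
)
from perfusim.physics import InvalidParameterError, sphere_volume


class TestKozeny:
    def test_reference_value(self):
        # d^2 eps^3 / (180 (1-eps)^2) at eps=0.3, d=100 um
        assert kozeny_permeability(0.3, 1e-4) == pytest.approx(3.061e-12, rel=1e-3)

    def test_monotone_in_porosity(self):
        assert kozeny_permeability(0.5, 1e-4) > kozeny_permeability(0.3, 1e-4)

    def test_vanishing_porosity_limit(self):
        assert kozeny_permeability(1e-6, 1e-4) < 1e-25

    @pytest.mark.parametrize("eps", [0.0, 1.0, -0.2, 1.5])
    def test_invalid_porosity(self, eps):
        with pytest.raises(InvalidParameterError):
            kozeny_permeability(eps, 1e-4)


class TestGeometries:
    @pytest.mark.parametrize(
        "name,volume_mL", [("realbio", 7.0), ("fluidizedbed", 4.8), ("quasivivo", 4.0)]
    )
    def test_reconstructed_volumes(self, name, volume_mL):
        geom = build_geometry(name)
        assert geom.volume() * 1e6 == pytest.approx(volume_mL, rel=0.10)

    def test_realbio_scaffold_thickness(self):
        geom = build_realbio()
        assert geom.dimensions["scaffold_thickness"] == pytest.approx(1e-3)
        ys = [c[1] for c in geom.regions["scaffold"].exterior.coords]
        assert max(ys) - min(ys) == pytest.approx(1e-3)

    def test_realbio_port_widths(self):
        geom = build_realbio()
        for tag in ("inlet_top", "inlet_bottom", "outlet_top", "outlet_bottom"):
            assert geom.boundary_length(tag) == pytest.approx(1e-3)

    def test_realbio_zero_scaffold_rejected(self):
        with pytest.raises(InvalidGeometryError):
            build_realbio({"scaffold_thickness": 0.0})

    def test_unknown_override_rejected(self):
        with pytest.raises(InvalidGeometryError):
            build_realbio({"no_such_dimension": 1.0})

    @pytest.mark.parametrize("variant,width", list(FB_WIDTHS.items()))
    def test_fb_width_variants(self, variant, width):
        geom = build_fluidizedbed(variant)
        assert geom.dimensions["width"] == pytest.approx(width)

    def test_fb_variant_ratio(self):
        narrow = build_fluidizedbed("narrow").dimensions["width"]
        orig = build_fluidizedbed("original").dimensions["width"]
        assert narrow / orig == pytest.approx(22.2 / 27.3)

    def test_fb_unknown_variant(self):
        with pytest.raises(InvalidParameterError):
            build_fluidizedbed("wavy")

    def test_fb_port_ids(self):
        geom = build_fluidizedbed()
        assert geom.boundary_length("inlet") == pytest.approx(1.5e-3)
        assert geom.boundary_length("outlet") == pytest.approx(3.0e-3)

    def test_qv_port_ids(self):
        geom = build_quasivivo()
        assert geom.boundary_length("inlet") == pytest.approx(1e-3)
        assert geom.boundary_length("outlet") == pytest.approx(2e-3)

    def test_qv_bed_holds_estimated_cell_load(self):
        # 1.5e6 cells at 50% v/v occupy ~12.6 uL of beads; the sparse floor
        # bed region must accommodate at least that bead volume
        geom = build_quasivivo()
        bead_volume = 1.5e6 * sphere_volume(20e-6) / 0.5
        assert geom.volume("bed") >= bead_volume

    def test_unknown_bioreactor(self):
        with pytest.raises(InvalidParameterError):
            build_geometry("spinnerflask")


class TestMesh:
    def test_refinement_multiplies_cells(self):
        geom = build_quasivivo()
        coarse = generate_mesh(geom, (4e-4, 2.5e-4))
        fine = generate_mesh(geom, (2e-4, 1.25e-4))
        assert fine.n_cells >= 3 * coarse.n_cells

    def test_quadrature_area_matches_geometry(self):
        for name in ("realbio", "fluidizedbed", "quasivivo"):
            geom = build_geometry(name)
            mesh = generate_mesh(geom)
            assert mesh.area() == pytest.approx(geom.area(), rel=0.02)

    def test_region_areas_stable_under_refinement(self):
        geom = build_fluidizedbed()
        a1 = generate_mesh(geom, (3e-4, 2.5e-4)).area("bed")
        a2 = generate_mesh(geom, (1.5e-4, 1.25e-4)).area("bed")
        assert a2 == pytest.approx(a1, rel=0.01)

    def test_resolution_too_coarse_for_inlet(self):
        geom = build_quasivivo()
        with pytest.raises(InvalidGeometryError):
            generate_mesh(geom, (2e-3, 2e-3))

    def test_boundary_tags_cover_all_ports(self):
        for name in ("realbio", "fluidizedbed", "quasivivo"):
            mesh = generate_mesh(build_geometry(name))
            for tag in mesh.geometry.boundaries:
                assert mesh.boundary_faces[tag].shape[0] > 0, (name, tag)

    def test_quality_report(self):
        mesh = generate_mesh(build_quasivivo())
        rep = mesh.quality_report()
        assert rep["cell_count"] == mesh.n_cells
        assert rep["min_angle_deg"] == 90.0
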