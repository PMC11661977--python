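"""Rendering modes, formats, determinism, and label content."""

import numpy as np
import pytest

import glycoplot as gp
from glycoplot.errors import ValidationError
from glycoplot.matching import annotate
from glycoplot.plotting import RenderSpec, render_aligned, render_mirrored, render_single
import glycoplot.plotting as plotting


@pytest.fixture
def annotated(glycopeptide_synth):
    return annotate(glycopeptide_synth.spectrum, glycopeptide_synth.identification)


class TestRenderSpecValidation:
    def test_bad_mode(self):
        with pytest.raises(ValidationError):
            RenderSpec(mode="fancy")

    def test_bad_range(self):
        with pytest.raises(ValidationError):
            RenderSpec(mz_range=(100.0, 50.0))

    def test_bad_format(self):
        with pytest.raises(ValidationError):
            RenderSpec(fmt="tiff")


class TestRenderSingle:
    def test_svg_contains_ion_labels_as_text(self, annotated, tmp_path):
        path = render_single(annotated, RenderSpec(), tmp_path / "out.svg")
        text = path.read_text()
        assert "y5" in text
        assert "Y0" in text

    def test_png_dimensions_match_size_and_dpi(self, annotated, tmp_path):
        from PIL import Image

        spec = RenderSpec(width=8.0, height=5.0, dpi=100)
        path = render_single(annotated, spec, tmp_path / "out.png")
        with Image.open(path) as img:
            assert img.size == (800, 500)

    def test_empty_mz_range_is_valid(self, annotated, tmp_path):
        spec = RenderSpec(mz_range=(9000.0, 9100.0))
        path = render_single(annotated, spec, tmp_path / "empty.svg")
        assert path.exists() and path.stat().st_size > 0

    @pytest.mark.parametrize("fmt", ["svg", "pdf", "eps", "png"])
    def test_all_formats_written(self, annotated, tmp_path, fmt):
        path = render_single(annotated, RenderSpec(fmt=fmt), tmp_path / f"out.{fmt}")
        assert path.stat().st_size > 0

    def test_mode_mismatch_rejected(self, annotated, tmp_path):
        with pytest.raises(ValidationError):
            render_single(annotated, RenderSpec(mode="mirrored"), tmp_path / "x.svg")


class TestDeterminism:
    @pytest.mark.parametrize("fmt", ["svg", "pdf"])
    def test_vector_output_byte_identical(self, annotated, tmp_path, fmt):
        p1 = render_single(annotated, RenderSpec(fmt=fmt), tmp_path / f"a.{fmt}")
        p2 = render_single(annotated, RenderSpec(fmt=fmt), tmp_path / f"b.{fmt}")
        assert p1.read_bytes() == p2.read_bytes()


class TestRenderMirrored:
    def test_same_spectrum_twice_is_symmetric(self, annotated, tmp_path, monkeypatch):
        captured = {}

        def fake_save(fig, path, spec):
            captured["fig"] = fig
            return path

        monkeypatch.setattr(plotting, "_save", fake_save)
        render_mirrored(annotated, annotated, RenderSpec(mode="mirrored"), tmp_path / "m.svg")
        ax = captured["fig"].axes[0]
        segments = [
            tuple(np.asarray(seg).ravel())
            for coll in ax.collections
            for seg in coll.get_segments()
        ]
        ups = sorted((x0, y1) for x0, _y0, _x1, y1 in segments if y1 > 0)
        downs = sorted((x0, -y1) for x0, _y0, _x1, y1 in segments if y1 < 0)
        assert ups == downs and len(ups) > 0

    def test_shared_axis_is_union_of_ranges(self, tmp_path, monkeypatch, biantennary_tree):
        truth1 = gp.synth_spectrum(
            gp.SynthSpec(gp.Peptide("PEPTIDEK"), precursor_charge=2, seed=1)
        )
        truth2 = gp.synth_spectrum(
            gp.SynthSpec(
                gp.Peptide("TPASDPHGDNLTYSVFYTK"),
                glycan_tree=biantennary_tree,
                precursor_charge=3,
                seed=2,
            )
        )
        a1 = annotate(truth1.spectrum, truth1.identification)
        a2 = annotate(truth2.spectrum, truth2.identification)
        captured = {}
        monkeypatch.setattr(
            plotting, "_save", lambda fig, path, spec: captured.update(fig=fig) or path
        )
        render_mirrored(a1, a2, RenderSpec(mode="mirrored"), tmp_path / "m.svg")
        lo, hi = captured["fig"].axes[0].get_xlim()
        all_mz = np.concatenate([a1.spectrum.mz, a2.spectrum.mz])
        assert lo <= all_mz.min() and hi >= all_mz.max()

    def test_site_discriminating_phospho_labels(self, tmp_path, registry):
        """Site localization: S6 vs S7 phosphopeptides give distinct b/y labels."""
        seq = "GNAEGSSDEEGKLVIDEPAK"
        truths = [
            gp.synth_spectrum(
                gp.SynthSpec(
                    gp.Peptide(seq, ((site, registry["Phospho"]),)),
                    precursor_charge=2,
                    seed=site,
                )
            )
            for site in (6, 7)
        ]
        anns = [annotate(t.spectrum, t.identification) for t in truths]
        path = render_mirrored(
            anns[0], anns[1], RenderSpec(mode="mirrored"), tmp_path / "phospho_sites.svg"
        )
        text = path.read_text()
        # the site-diagnostic b6 ion differs in m/z between the two, and
        # neutral-loss satellites are drawn
        assert "b6" in text and "H3PO4" in text


class TestRenderAligned:
    def test_three_panes_share_xlim(self, annotated, tmp_path, monkeypatch):
        captured = {}
        monkeypatch.setattr(
            plotting, "_save", lambda fig, path, spec: captured.update(fig=fig) or path
        )
        render_aligned([annotated] * 3, RenderSpec(mode="aligned"), tmp_path / "a.svg")
        xlims = {ax.get_xlim() for ax in captured["fig"].axes}
        assert len(captured["fig"].axes) == 3 and len(xlims) == 1

    def test_single_spectrum_rejected(self, annotated, tmp_path):
        with pytest.raises(ValidationError):
            render_aligned([annotated], RenderSpec(mode="aligned"), tmp_path / "a.svg")

    def test_chimeric_comparison_stacks(self, tmp_path, biantennary_tree):
        """Cross-tool comparison: one scan, three tool assignments, one figure."""
        truth = gp.synth_spectrum(
            gp.SynthSpec(
                gp.Peptide("TPASDPHGDNLTYSVFYTK"),
                glycan_tree=biantennary_tree,
                precursor_charge=3,
                seed=5,
            )
        )
        comps = ["Hex(4)HexNAc(5)Fuc(2)", "Hex(4)HexNAc(5)NeuAc(1)", "Hex(4)HexNAc(5)Fuc(2)"]
        anns = [
            annotate(
                truth.spectrum,
                gp.Identification(
                    truth.spectrum.scan_number,
                    truth.identification.peptide,
                    glycan_composition=gp.parse_composition(c),
                ),
            )
            for c in comps
        ]
        path = render_aligned(anns, RenderSpec(mode="aligned"), tmp_path / "cross_tool.svg")
        text = path.read_text()
        assert "Fuc(2)" in text and "NeuAc(1)" in text
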