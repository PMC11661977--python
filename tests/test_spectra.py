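"""mzML reading, identification tables with dialects, scan-number pairing."""

import numpy as np
import pytest

import glycoplot as gp
from glycoplot.errors import SchemaError
from glycoplot.fragments import DissociationMethod


def _two_scan_mzml(tmp_path, activations=(DissociationMethod.HCD, DissociationMethod.ETHCD)):
    specs = [
        gp.SynthSpec(
            peptide=gp.Peptide("PEPTIDEK"),
            precursor_charge=2,
            activation=act,
            seed=k,
            scan_number=1000 + k,
        )
        for k, act in enumerate(activations)
    ]
    results = [gp.synth_spectrum(s) for s in specs]
    path = tmp_path / "two.mzML"
    gp.write_mzml([r.spectrum for r in results], path)
    return path, results


class TestReadMzml:
    def test_roundtrip_counts_and_scans(self, tmp_path):
        path, results = _two_scan_mzml(tmp_path)
        read = list(gp.read_mzml(path))
        assert [s.scan_number for s in read] == [1000, 1001]
        for got, expected in zip(read, results):
            assert len(got) == len(expected.spectrum)
            assert got.activation == expected.spectrum.activation
            assert got.precursor_charge == expected.spectrum.precursor_charge
            # float32 encoding keeps ~7 significant digits
            np.testing.assert_allclose(got.mz, expected.spectrum.mz, rtol=1e-6)

    @pytest.mark.parametrize("method", list(DissociationMethod))
    def test_activation_cv_roundtrip(self, tmp_path, method):
        spec = gp.SynthSpec(
            peptide=gp.Peptide("PEPTIDEK"), precursor_charge=2, activation=method, seed=1
        )
        r = gp.synth_spectrum(spec)
        path = tmp_path / "one.mzML"
        gp.write_mzml([r.spectrum], path)
        (got,) = gp.read_mzml(path)
        assert got.activation == method

    def test_unknown_activation_defaults_hcd(self, tmp_path, caplog):
        spec = gp.SynthSpec(
            peptide=gp.Peptide("PEPTIDEK"),
            precursor_charge=2,
            activation=DissociationMethod.ETD,
            seed=1,
        )
        r = gp.synth_spectrum(spec)
        path = tmp_path / "generic.mzML"
        gp.write_mzml([r.spectrum], path, generic_activation=True)
        with caplog.at_level("WARNING"):
            (got,) = gp.read_mzml(path)
        assert got.activation == DissociationMethod.HCD
        assert any("activation" in rec.message for rec in caplog.records)

    def test_empty_file_errors(self, tmp_path):
        path = tmp_path / "empty.mzML"
        path.write_text("")
        with pytest.raises(IOError):
            list(gp.read_mzml(path))

    def test_truncated_xml_errors(self, tmp_path):
        path, _ = _two_scan_mzml(tmp_path)
        text = path.read_text()
        (tmp_path / "trunc.mzML").write_text(text[: len(text) // 2])
        with pytest.raises(IOError):
            list(gp.read_mzml(tmp_path / "trunc.mzML"))

    def test_peaks_sorted_ascending(self, tmp_path):
        path, _ = _two_scan_mzml(tmp_path)
        for s in gp.read_mzml(path):
            assert np.all(np.diff(s.mz) >= 0)


class TestReadResults:
    def test_generic_csv_with_composition(self, tmp_path):
        path = tmp_path / "ids.csv"
        path.write_text(
            "scan,peptide,glycan\n1000,TPASDPHGDNLTYSVFYTK,Hex(4)HexNAc(5)Fuc(2)\n"
        )
        (ident,) = gp.read_results(path)
        assert ident.scan_number == 1000
        assert ident.peptide.sequence == "TPASDPHGDNLTYSVFYTK"
        assert dict(ident.glycan_composition) == {"Hex": 4, "HexNAc": 5, "Fuc": 2}
        assert ident.glycan_tree is None

    def test_missing_scan_column_is_schema_error(self, tmp_path):
        path = tmp_path / "ids.csv"
        path.write_text("peptide,glycan\nPEPTIDEK,\n")
        with pytest.raises(SchemaError, match="scan"):
            gp.read_results(path)

    def test_wurcs_cell_dispatched_to_structure_parser(self, tmp_path):
        path = tmp_path / "ids.csv"
        path.write_text(
            'scan,peptide,glycan\n7,PEPTIDEK,"WURCS=2.0/1,1,0/[u2122h]/1/"\n'
        )
        (ident,) = gp.read_results(path)
        assert ident.glycan_tree is not None
        assert dict(ident.glycan_composition) == {"Hex": 1}

    def test_glycoct_cell_with_embedded_newlines(self, tmp_path):
        core = gp.to_glycoct(gp.nglycan_core()).replace('"', '""')
        path = tmp_path / "ids.csv"
        path.write_text(f'scan,peptide,glycan\n3,PEPTIDEK,"{core}"\n')
        (ident,) = gp.read_results(path)
        assert dict(ident.glycan_composition) == {"Hex": 3, "HexNAc": 2}

    def test_bad_row_skipped_with_log(self, tmp_path, caplog):
        path = tmp_path / "ids.csv"
        path.write_text("scan,peptide\n1,PEPTIDEK\nnotascan,B@D\n2,GGGG\n")
        with caplog.at_level("WARNING"):
            idents = gp.read_results(path)
        assert [i.scan_number for i in idents] == [1, 2]
        assert any("row 3" in rec.message for rec in caplog.records)

    def test_tool_dialect_column_map(self, tmp_path):
        path = tmp_path / "pg.csv"
        path.write_text(
            "Scan,Peptide,GlycanComposition,Charge\n"
            "55,TPASDPHGDNLTYSVFYTK,Hex(4)HexNAc(5)NeuAc(1),3\n"
        )
        (ident,) = gp.read_results(path, dialect="pglyco3")
        assert ident.scan_number == 55
        assert ident.source_tool == "pglyco3"
        assert dict(ident.glycan_composition) == {"Hex": 4, "HexNAc": 5, "NeuAc": 1}

    def test_custom_dialect_config(self, tmp_path):
        cfg = tmp_path / "dialect.cfg"
        cfg.write_text("scan=MyScan\npeptide=Seq\n")
        data = tmp_path / "ids.csv"
        data.write_text("MyScan,Seq\n12,PEPTIDEK\n")
        dialect = gp.spectra.load_dialect_config(cfg)
        (ident,) = gp.read_results(data, dialect)
        assert ident.scan_number == 12

    def test_modified_peptide_column(self, tmp_path, registry):
        path = tmp_path / "ids.csv"
        path.write_text("scan,peptide\n4,GNAEGS(Phospho)SDEEGKLVIDEPAK\n")
        (ident,) = gp.read_results(path, registry=registry)
        assert ident.peptide.modifications[0][0] == 6


class TestPair:
    def _spectra(self, scans):
        return [
            gp.Spectrum(n, 2, 500.0, 2, DissociationMethod.HCD, [100.0], [1.0])
            for n in scans
        ]

    def _idents(self, scans):
        return [gp.Identification(n, gp.Peptide("PEPTIDEK")) for n in scans]

    def test_join_and_unmatched_report(self):
        report = gp.pair(self._spectra([1, 2, 3]), self._idents([1, 3, 9]))
        assert len(report.pairs) == 2
        assert [i.scan_number for i in report.unmatched_identifications] == [9]

    def test_duplicate_scan_in_results_gives_two_pairs(self):
        report = gp.pair(self._spectra([5]), self._idents([5, 5]))
        assert len(report.pairs) == 2

    def test_empty_results(self):
        report = gp.pair(self._spectra([1]), [])
        assert report.pairs == [] and report.unmatched_identifications == []
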