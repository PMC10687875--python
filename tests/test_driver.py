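"""Configuration, assembly bookkeeping, model API and CLI."""
import json

import numpy as np
import pytest
from click.testing import CliRunner

from lnocc import (LNOCCSDT, ThresholdConfig, generate_fixture,
                   run_lno_ccsdt)
from lnocc.cli import main as cli_main
from lnocc.driver import TABLE_KEYWORDS


def test_normal_preset_matches_published_defaults():
    cfg = ThresholdConfig.normal()
    assert cfg.eps_o == 1e-5
    assert cfg.eps_v == 1e-6          # ratio eps_o/eps_v = 10
    assert cfg.eps_w == 1e-5
    assert cfg.T_EDo == 0.9999
    assert cfg.eps_naf == 1e-2
    assert cfg.T_LT == 1e-2
    assert cfg.g_w == 5.0
    assert cfg.h_w == 50.0


def test_tight_preset_tightens_by_one_decade():
    t = ThresholdConfig.tight()
    assert (t.eps_o, t.eps_v, t.eps_w) == (1e-6, 1e-7, 1e-6)


def test_yaml_config_roundtrip(tmp_path):
    path = tmp_path / "cfg.yaml"
    path.write_text("lnoepso: 1.0e-4\nwpairtol: 2.0e-5\nlaptol: 1.0e-3\n")
    cfg = ThresholdConfig.from_yaml(path)
    assert cfg.eps_o == 1e-4
    assert cfg.eps_w == 2e-5
    assert cfg.T_LT == 1e-3
    assert set(TABLE_KEYWORDS.values()) <= set(
        ThresholdConfig.__dataclass_fields__)


@pytest.fixture(scope="module")
def water_fit(water_ref, water_df):
    model = LNOCCSDT(generate_fixture("water"), basis="svdz")
    model._ref, model._df = water_ref, water_df
    return model.fit()


def test_assembly_identities_hold_exactly(water_fit):
    """Totals are exact sums of the stored per-domain pieces plus the
    distant-pair energy (bookkeeping identities)."""
    rep = water_fit.report
    e = sum(d.e_ccsd + d.e_t + d.e_mp2_ed - d.e_mp2_lis
            for d in rep.domains) + rep.distant_pair_energy
    assert rep.corr_energy == pytest.approx(e, abs=1e-14)
    lmp2 = sum(d.e_mp2_ed for d in rep.domains) + rep.distant_pair_energy
    assert rep.corr_lmp2 == pytest.approx(lmp2, abs=1e-14)
    assert rep.total_energy == rep.scf_energy + rep.corr_energy


def test_report_serialization_and_summary(water_fit):
    payload = json.loads(water_fit.to_json())
    assert payload["schema_version"] == 1
    assert "corr_energy" in payload and len(payload["domains"]) > 0
    text = water_fit.summary()
    assert "LNO-CCSD(T)" in text and "E(total)" in text
    frame = water_fit.domain_frame()
    assert len(frame) == len(water_fit.report.domains)


def test_rerun_is_deterministic(water_ref, water_df, water_fit):
    rep2 = run_lno_ccsdt(water_ref, ThresholdConfig.normal(), water_df)
    assert rep2.corr_energy == water_fit.corr_energy   # bitwise


def test_cli_missing_file_exits_nonzero(tmp_path):
    runner = CliRunner()
    res = runner.invoke(cli_main, [str(tmp_path / "nope.xyz")])
    assert res.exit_code != 0


def test_cli_runs_and_writes_report(tmp_path):
    mol = generate_fixture("hydroxyl")
    xyz = tmp_path / "oh.xyz"
    xyz.write_text(mol.to_xyz("hydroxyl radical"))
    out = tmp_path / "report.json"
    csv = tmp_path / "domains.csv"
    runner = CliRunner()
    res = runner.invoke(cli_main, [str(xyz), "-m", "2", "--basis", "sto-3g",
                                   "-o", str(out), "--domains-csv",
                                   str(csv)])
    assert res.exit_code == 0, res.output
    payload = json.loads(out.read_text())
    assert payload["corr_energy"] < 0.0
    assert payload["config"]["preset"] == "normal"
    assert csv.exists()


def test_qro_reference_pipeline_close_to_rohf():
    mol = generate_fixture("methyl")
    cfg = ThresholdConfig.normal()
    e, e_scf = {}, {}
    for mode in ("rohf", "uhf_qro"):
        res = LNOCCSDT(mol, basis="sto-3g", config=cfg,
                       reference_mode=mode).fit()
        e[mode] = res.total_energy
        e_scf[mode] = res.scf_energy
    # QRO determinant agrees with direct ROHF to chemical tolerance
    assert abs(e_scf["rohf"] - e_scf["uhf_qro"]) < 1e-4
    assert abs(e["rohf"] - e["uhf_qro"]) < 1e-3
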