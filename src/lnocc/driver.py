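"""Pipeline driver: configuration, domain routing, assembly, model API.

The user-facing entry point is the :class:`LNOCCSDT` model object: build
it from a molecule (or XYZ file), call :meth:`LNOCCSDT.fit`, and read
the per-domain contributions, diagnostics and totals off the returned
:class:`LNOCCSDTResults`.
"""
from __future__ import annotations

import dataclasses
import itertools
import json

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .ccsd import ccsd_contribution, solve_ccsd
from .domains import DomainBuilder
from .eddomain import (EDIntegrals, assemble_ed, build_fock_offdiagonal,
                       denominator_range, ed_mp2_energy, ed_quadrature,
                       mp1_amplitudes, transform_df_integrals)
from .laplace import laplace_quadrature
from .lis import (build_lis, central_spin_orbital_projectors,
                  lis_spin_orbital_blocks)
from .lno import occupied_density_fragment, select_lnos
from .localize import localize_boys_restricted
from .mol import Molecule
from .pairs import (DEFAULT_FW, MultipoleIntegrals, classify_pairs,
                    exact_pd_pair_energy, multipole_pair_energy)
from .scf import DFTensors, ReferenceState, build_reference
from .triples import (triples_contribution_explicit,
                      triples_contributions_laplace)

TABLE_KEYWORDS = {
    "lnoepso": "eps_o", "lnoepsv": "eps_v", "wpairtol": "eps_w",
    "bpedo": "T_EDo", "naf_cor": "eps_naf", "laptol": "T_LT",
    "epairscale": "g_w", "epairestfact": "h_w",
}


@dataclasses.dataclass
class ThresholdConfig:
    """Truncation thresholds; the Normal preset is the method's default."""
    eps_o: float = 1e-5
    eps_v: float | None = None          # default: eps_o / 10
    eps_w: float = 1e-5                 # hartree
    T_EDo: float = 0.9999
    T_PDo: float = 0.999
    T_PDv: float = 0.98
    T_0: float = 0.985
    eps_naf: float = 1e-2               # hartree
    T_LT: float = 1e-2
    g_w: float = 5.0
    h_w: float = 50.0                   # hartree^-1
    f_w: dict | None = None
    preset: str = "custom"
    spin_polarization_approx: bool = False
    pair_energy_mode: str = "multipole"  # "multipole" | "exact_pd"
    denominator_factorization: str = "laplace"  # "laplace"|"cholesky"|"exact"
    ccsd_conv_tol: float = 1e-8
    ccsd_max_iter: int = 100

    def __post_init__(self):
        if self.eps_v is None:
            # one decade below eps_o, cleaned of float-division noise
            self.eps_v = float(f"{self.eps_o / 10.0:.6g}")
        if self.f_w is None:
            self.f_w = dict(DEFAULT_FW)

    @classmethod
    def normal(cls, **over) -> "ThresholdConfig":
        return cls(preset="normal", **over)

    @classmethod
    def tight(cls, **over) -> "ThresholdConfig":
        return cls(eps_o=1e-6, eps_v=1e-7, eps_w=1e-6, preset="tight",
                   **over)

    @classmethod
    def no_truncation(cls, **over) -> "ThresholdConfig":
        """All local truncations disabled (canonical-limit runs)."""
        defaults = dict(eps_o=0.0, eps_v=0.0, eps_w=0.0, T_EDo=1.0,
                        T_PDo=1.0, T_PDv=1.0, T_0=1.0, eps_naf=0.0,
                        preset="no_truncation", pair_energy_mode="exact_pd",
                        denominator_factorization="exact")
        defaults.update(over)
        return cls(**defaults)

    @classmethod
    def from_yaml(cls, path) -> "ThresholdConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        preset = raw.pop("preset", "custom")
        base = {"normal": cls.normal, "tight": cls.tight,
                "custom": cls}[preset]
        kwargs = {}
        for key, val in raw.items():
            kwargs[TABLE_KEYWORDS.get(key, key)] = val
        cfg = base(**kwargs) if preset != "custom" else cls(**kwargs)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["f_w"] = {"-".join(k): v for k, v in self.f_w.items()}
        return d


@dataclasses.dataclass
class DomainResult:
    central: int
    origin: str
    path: str                     # "unrestricted" | "spin_averaged"
    e_mp2_ed: float
    e_mp2_lis: float
    e_ccsd: float
    e_t: float
    n_ed_atoms: int
    n_ed_ao: int
    n_ed_occ: int
    n_ed_pao: int
    n_lis_occ: int
    n_lis_virt: int
    n_naf: int
    n_aux: int
    ccsd_iterations: int
    lno_expansion_error: float

    @property
    def e_ccsdt(self) -> float:
        return self.e_ccsd + self.e_t


@dataclasses.dataclass
class EnergyReport:
    domains: list
    distant_pair_energy: float
    n_strong_pairs: int
    n_distant_pairs: int
    scf_energy: float
    config: ThresholdConfig

    @property
    def corr_lmp2(self) -> float:
        """Local MP2 correlation energy (assembly side product)."""
        return sum(d.e_mp2_ed for d in self.domains) \
            + self.distant_pair_energy

    @property
    def corr_energy(self) -> float:
        return sum(d.e_ccsdt + d.e_mp2_ed - d.e_mp2_lis
                   for d in self.domains) + self.distant_pair_energy

    @property
    def total_energy(self) -> float:
        return self.scf_energy + self.corr_energy

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(d) for d in self.domains])

    def to_json(self) -> str:
        return json.dumps({
            "schema_version": 1,
            "package_version": _pkg_version,
            "scf_energy": self.scf_energy,
            "corr_energy": self.corr_energy,
            "total_energy": self.total_energy,
            "corr_lmp2": self.corr_lmp2,
            "distant_pair_energy": self.distant_pair_energy,
            "n_strong_pairs": self.n_strong_pairs,
            "n_distant_pairs": self.n_distant_pairs,
            "config": self.config.to_dict(),
            "domains": [dataclasses.asdict(d) for d in self.domains],
        }, indent=1)


def route_domain(ed, config: ThresholdConfig) -> str:
    """Spin-averaged path iff the ED has no SOMO and the long-range
    spin-polarization approximation is enabled."""
    return "spin_averaged" if ed.spin_averaged else "unrestricted"


def run_domain(builder, ref, df, pair_list, f_od, central,
               config: ThresholdConfig, log=None) -> DomainResult:
    ed = assemble_ed(builder, central, pair_list, T_EDo=config.T_EDo,
                     T_0=config.T_0,
                     spin_polarization_approx=config.spin_polarization_approx)
    ints = transform_df_integrals(ed, df)
    fact = config.denominator_factorization
    quad = None if fact == "exact" else ed_quadrature(ed, config.T_LT)
    amps = mp1_amplitudes(ed, ints, quad, factorization=fact)
    e_mp2_ed = ed_mp2_energy(ed, ints, amps, f_od)

    occ_frag = occupied_density_fragment(ed, amps)
    lnos = select_lnos(ed, occ_frag, amps, config.eps_o, config.eps_v)
    lis = build_lis(ed, ref, df, lnos, eps_naf=config.eps_naf)
    lis_ints = EDIntegrals(lis.b_ov, lis.b_oo, lis.b_vv, np.zeros(0))
    if fact == "exact":
        quad_lis = None
    else:
        lo, hi = denominator_range(lis)
        quad_lis = laplace_quadrature(lo, hi, config.T_LT)
    amps_lis = mp1_amplitudes(lis, lis_ints, quad_lis, factorization=fact)
    e_mp2_lis = ed_mp2_energy(lis, lis_ints, amps_lis, f_od)

    blocks = lis_spin_orbital_blocks(lis, ed, ref)
    cc = solve_ccsd(blocks, conv_tol=config.ccsd_conv_tol,
                    max_iter=config.ccsd_max_iter)
    projs = central_spin_orbital_projectors(lis)
    e_ccsd = sum(ccsd_contribution(blocks, cc, u) for u in projs)
    if fact == "exact":
        e_t = sum(triples_contribution_explicit(blocks, cc.t1, cc.t2, u)
                  for u in projs)
    else:
        lo3 = 3.0 * (blocks.eps_v.min() - blocks.eps_o.max())
        hi3 = 3.0 * (blocks.eps_v.max() - blocks.eps_o.min())
        quad3 = laplace_quadrature(lo3, hi3, config.T_LT)
        e_t = sum(triples_contributions_laplace(blocks, cc.t1, cc.t2,
                                                quad3, projs))
    return DomainResult(
        central=central, origin=builder.lmos.origin[central],
        path=route_domain(ed, config),
        e_mp2_ed=e_mp2_ed, e_mp2_lis=e_mp2_lis, e_ccsd=e_ccsd, e_t=e_t,
        n_ed_atoms=len(ed.atoms), n_ed_ao=len(ed.ao_idx),
        n_ed_occ=ed.n_occ, n_ed_pao=ed.pao_coeff.shape[1],
        n_lis_occ=lis.n_occ, n_lis_virt=lis.virt_lno_coeff.shape[1],
        n_naf=lis.naf.n_kept, n_aux=len(ints.aux_idx),
        ccsd_iterations=cc.iterations,
        lno_expansion_error=lis.lno_expansion_error)


def compute_pair_list(builder, ref, df, mpints, config: ThresholdConfig):
    energies = {}
    nlmo = builder.lmos.n
    for k, l in itertools.combinations(range(nlmo), 2):
        if config.pair_energy_mode == "exact_pd":
            energies[(k, l)] = exact_pd_pair_energy(
                builder, df, k, l, config.T_PDo, config.T_PDv)
        else:
            energies[(k, l)] = multipole_pair_energy(
                builder, mpints, k, l, config.T_PDo, config.T_PDv)
    return classify_pairs(builder, energies, config.eps_w, config.g_w,
                          config.h_w, f_w=config.f_w, T_PDo=config.T_PDo)


def run_lno_ccsdt(ref: ReferenceState, config: ThresholdConfig | None = None,
                  df: DFTensors | None = None, verbose: bool = False,
                  prepared: tuple | None = None) -> EnergyReport:
    """Full restricted open-shell LNO-CCSD(T) pipeline over a reference.

    `prepared` optionally carries a (DomainBuilder, PairList) pair so that
    localization and pair classification can be shared between runs that
    differ only in downstream thresholds (e.g. LNO threshold scans).
    """
    config = config or ThresholdConfig.normal()
    if df is None:
        df = DFTensors(ref.basis, ref.aux)
    if prepared is not None:
        builder, pair_list = prepared
        lmos = builder.lmos
    else:
        lmos = localize_boys_restricted(ref)
        builder = DomainBuilder(ref, lmos)
        mpints = MultipoleIntegrals(ref)
        pair_list = compute_pair_list(builder, ref, df, mpints, config)
    f_od = build_fock_offdiagonal(ref)
    domains, failures = [], []
    for central in range(lmos.n):        # deterministic ascending order
        try:
            domains.append(run_domain(builder, ref, df, pair_list, f_od,
                                      central, config))
        except Exception as exc:         # noqa: BLE001 - reported, re-raised
            failures.append((central, exc))
        if verbose and domains:
            d = domains[-1]
            print(f"  domain {d.central:3d} [{d.origin}] "
                  f"ccsd {d.e_ccsd:+.8f} (T) {d.e_t:+.8f} "
                  f"lis {d.n_lis_occ}x{d.n_lis_virt}")
    if failures:
        msgs = "; ".join(f"LMO {c}: {e}" for c, e in failures)
        raise RuntimeError(
            f"{len(failures)} domain(s) failed, no total energy emitted: "
            f"{msgs}") from failures[0][1]
    n_strong = sum(1 for p in pair_list.pairs
                   if p.classification == "strong")
    return EnergyReport(domains, pair_list.distant_energy, n_strong,
                        len(pair_list.pairs) - n_strong, ref.scf_energy,
                        config)


def spin_polarization_comparison(ref: ReferenceState,
                                 config: ThresholdConfig | None = None,
                                 df: DFTensors | None = None):
    """Correlation energies with the long-range spin-polarization
    approximation off and on.

    The approximation replaces the per-spin Fock matrices by their average
    only in EDs containing no SOMO, so domains with a SOMO in their ED are
    bitwise identical in both runs; they are computed once and shared.
    Returns (report_off, report_on).
    """
    config = config or ThresholdConfig.normal()
    if df is None:
        df = DFTensors(ref.basis, ref.aux)
    cfg_off = dataclasses.replace(config, spin_polarization_approx=False)
    cfg_on = dataclasses.replace(config, spin_polarization_approx=True)
    lmos = localize_boys_restricted(ref)
    builder = DomainBuilder(ref, lmos)
    mpints = MultipoleIntegrals(ref)
    pair_list = compute_pair_list(builder, ref, df, mpints, cfg_off)
    f_od = build_fock_offdiagonal(ref)
    doms_off, doms_on = [], []
    for central in range(lmos.n):
        d_off = run_domain(builder, ref, df, pair_list, f_od, central,
                           cfg_off)
        doms_off.append(d_off)
        ed = assemble_ed(builder, central, pair_list, T_EDo=cfg_on.T_EDo,
                         T_0=cfg_on.T_0, spin_polarization_approx=True)
        if ed.spin_averaged:
            doms_on.append(run_domain(builder, ref, df, pair_list, f_od,
                                      central, cfg_on))
        else:
            doms_on.append(dataclasses.replace(d_off))
    n_strong = sum(1 for p in pair_list.pairs
                   if p.classification == "strong")
    n_dist = len(pair_list.pairs) - n_strong
    rep_off = EnergyReport(doms_off, pair_list.distant_energy, n_strong,
                           n_dist, ref.scf_energy, cfg_off)
    rep_on = EnergyReport(doms_on, pair_list.distant_energy, n_strong,
                          n_dist, ref.scf_energy, cfg_on)
    return rep_off, rep_on


# ------------------------------------------------------------- model API

class LNOCCSDT:
    """Restricted open-shell LNO-CCSD(T) model over a molecular system.

    Parameters
    ----------
    mol : Molecule
        Geometry, charge and spin multiplicity.
    basis : str
        Orbital basis set name ("svdz" or "sto-3g").
    config : ThresholdConfig, optional
        Truncation thresholds (Normal preset when omitted).
    reference_mode : str
        "rohf" or "uhf_qro".

    Examples
    --------
    >>> from lnocc import LNOCCSDT, generate_fixture
    >>> model = LNOCCSDT(generate_fixture("methyl"), basis="svdz")
    >>> res = model.fit()
    >>> print(res.summary())          # doctest: +SKIP
    """

    def __init__(self, mol: Molecule, basis: str = "svdz",
                 config: ThresholdConfig | None = None,
                 reference_mode: str = "rohf"):
        self.mol = mol
        self.basis = basis
        self.config = config or ThresholdConfig.normal()
        self.reference_mode = reference_mode
        self._ref = None
        self._df = None

    @classmethod
    def from_xyz(cls, path, charge=0, multiplicity=1, **kw) -> "LNOCCSDT":
        return cls(Molecule.from_xyz(path, charge, multiplicity), **kw)

    @property
    def reference(self) -> ReferenceState:
        if self._ref is None:
            self._ref = build_reference(self.mol, self.basis,
                                        mode=self.reference_mode)
        return self._ref

    @property
    def df(self) -> DFTensors:
        if self._df is None:
            self._df = DFTensors(self.reference.basis, self.reference.aux)
        return self._df

    def fit(self, verbose: bool = False) -> "LNOCCSDTResults":
        report = run_lno_ccsdt(self.reference, self.config, self.df,
                               verbose=verbose)
        return LNOCCSDTResults(self, report)


class LNOCCSDTResults:
    """Fitted results: totals, per-domain contributions, diagnostics."""

    def __init__(self, model: LNOCCSDT, report: EnergyReport):
        self.model = model
        self.report = report

    @property
    def scf_energy(self) -> float:
        return self.report.scf_energy

    @property
    def corr_energy(self) -> float:
        return self.report.corr_energy

    @property
    def corr_lmp2(self) -> float:
        return self.report.corr_lmp2

    @property
    def total_energy(self) -> float:
        return self.report.total_energy

    def domain_frame(self) -> pd.DataFrame:
        return self.report.to_frame()

    def to_json(self) -> str:
        return self.report.to_json()

    def summary(self) -> str:
        r = self.report
        mol = self.model.mol
        lines = [
            "Restricted open-shell LNO-CCSD(T)",
            "=" * 49,
            f"formula            {''.join(mol.symbols)}",
            f"basis              {self.model.basis}",
            f"preset             {r.config.preset}",
            f"reference          {self.model.reference_mode}"
            f" (multiplicity {mol.multiplicity})",
            f"domains            {len(r.domains)}",
            f"strong / distant   {r.n_strong_pairs} / {r.n_distant_pairs}",
            f"spin-averaged EDs  "
            f"{sum(1 for d in r.domains if d.path == 'spin_averaged')}",
            "-" * 49,
            f"E(SCF)             {r.scf_energy:+.10f} Eh",
            f"E(corr, LMP2)      {r.corr_lmp2:+.10f} Eh",
            f"E(corr, LNO-CCSD(T)) {r.corr_energy:+.10f} Eh",
            f"E(total)           {r.total_energy:+.10f} Eh",
        ]
        return "\n".join(lines)
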