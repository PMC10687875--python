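# lnocc

Restricted open-shell local natural orbital CCSD(T) at desk scale.

## The problem

Coupled-cluster theory with singles, doubles and perturbative triples,
CCSD(T), is the standard route to chemically accurate correlation
energies for single-reference molecules, but its canonical cost grows as
the seventh power of system size — and open-shell species (radicals,
ionized molecules, transition states) are hit hardest, because
unrestricted formalisms roughly triple the work.  Local correlation
methods restore feasibility by exploiting the short range of dynamic
correlation: the energy is split into contributions of localized
occupied orbitals, and each contribution is evaluated in a compact,
orbital-specific subspace.

`lnocc` implements the local natural orbital (LNO) flavor of this idea
for high-spin open-shell molecules built on restricted open-shell
references, as a small, fully testable Python library:

* ROHF (or UHF-derived quasi-restricted-orbital) references with
  restricted Boys-localized occupied orbitals, keeping doubly occupied
  (DOMO) and singly occupied (SOMO) subspaces separate — SOMOs play the
  dual role of occupied spin-up and virtual spin-down orbitals;
* projected atomic orbitals (PAOs), Boughton–Pulay atom lists, and
  fourth-order multipole MP2 pair-energy estimates that classify orbital
  pairs as strong or distant without any distance cutoff, including a
  Mulliken-overlap rescue for borderline pairs;
* extended domains per central localized orbital with density-fitted
  integrals, iteration-free MP1 amplitudes through Laplace (or pivoted
  Cholesky) factorized energy denominators, and domain MP2 energies
  whose singles stem solely from the off-diagonal Fock matrix of the
  non-self-consistent restricted reference;
* local natural orbitals from MP1 density-matrix fragments (with
  central-orbital and SOMO blocks protected from truncation), the
  PAO′/LNO′ two-external integral transformation, and natural auxiliary
  function (NAF) compression shared by both spin channels;
* spin-orbital CCSD with a general (non-diagonal) Fock matrix in each
  local interacting subspace, exact per-orbital energy partitioning, and
  Laplace-transform perturbative triples evaluated only for the central
  orbital;
* a long-range spin-polarization approximation that treats SOMO-free
  domains with spin-averaged Fock matrices.

The assembled correlation energy is

```
E_corr = Σ_L [ δE_L^CCSD(T) + ( δE_L^MP2(ED) − δE_L^MP2(LIS) ) ] + Σ_distant ε_kl
```

where L runs over localized occupied orbitals, δE_L^CCSD(T) is orbital
L's CCSD(T) contribution in its local interacting subspace (LIS), the
bracketed MP2 difference corrects the LNO truncation at the MP2 level in
the extended domain (ED), and distant pairs enter through their
multipole-estimated MP2 pair energies ε_kl.  A local MP2 energy falls
out of the same assembly as a side product.

Everything down to the Gaussian integrals (a McMurchie–Davidson engine
JIT-compiled with numba), the SCF solvers and the density fitting is
part of the package, so the whole pipeline — and the brute-force
canonical DF-CCSD(T) oracle used to validate it — runs from a plain
scientific Python stack with no quantum chemistry backend.

## Worked example

```python
from lnocc import LNOCCSDT, ThresholdConfig, generate_fixture

model = LNOCCSDT(generate_fixture("methyl"), basis="svdz",
                 config=ThresholdConfig.normal())
res = model.fit()
print(res.summary())
```

prints

```
Restricted open-shell LNO-CCSD(T)
=================================================
formula            CHHH
basis              svdz
preset             normal
reference          rohf (multiplicity 2)
domains            4
strong / distant   6 / 0
spin-averaged EDs  0
-------------------------------------------------
E(SCF)             -39.1055753584 Eh
E(corr, LMP2)      -0.0745409141 Eh
E(corr, LNO-CCSD(T)) -0.0957506502 Eh
E(total)           -39.2013260086 Eh
```

The methyl radical has four correlated localized orbitals (three C–H
bonds and the singly occupied 2p orbital), each with its own domain; on
a molecule this small every orbital pair is strong, the domains span the
whole molecule, and the assembled LNO-CCSD(T) correlation energy agrees
with the package's brute-force canonical CCSD(T) to better than
1e-7 hartree.  `res.domain_frame()` returns the per-domain table
(contributions, domain sizes, NAF counts, CCSD iteration counts) as a
pandas DataFrame, and `res.to_json()` serializes the full report.

The same pipeline is exposed as a command-line tool:

```bash
lnocc geometry.xyz --multiplicity 2 --basis svdz -o report.json
```

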