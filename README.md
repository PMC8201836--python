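# rodplan

A planning toolkit for **virtual-rod spatially fractionated radiotherapy
(SFRT)** boosts. It targets the clinical situation in which a brachytherapy
boost for locally advanced cervical cancer is not available or not feasible,
and the boost must instead be delivered with external photon beams while still
producing the strongly heterogeneous, brachytherapy-like dose pattern inside
the target.

The package is aimed at medical physicists and planning researchers who want
to prototype and evaluate the technique without patient data: every input is a
seeded synthetic pelvic phantom.

## What it does

- **Virtual rod generation** — the core idea. Cylindrical "rods" (default:
  diameter 5.0 mm, center-to-center pitch 15.0 mm, i.e. a 10 mm edge gap;
  three rods, one central) are laid out on a square lattice perpendicular to a
  freely tilted axis (angles in the ZX and ZY patient planes) and clipped to
  the clinical target volume (CTV). "Bending" rods — tubes swept along a
  natural cubic spline through user-chosen seed points — follow curved
  anatomy such as the uterus. A "valley" (cooling) structure is the CTV minus
  the margin-expanded rods.
- **Surrogate dose optimization** for three strategies: `SFRT_1`
  (peak-and-valley: rods driven to ≥ 60 Gy, valley held ≤ 45 Gy), `SFRT_2`
  (peak-only) and `SBRT` (uniform coverage). Dose is modelled as a
  nonnegative intensity convolved with a Gaussian deliverability kernel
  (σ = 3 mm) and fitted by projected gradient descent.
- **Evaluation chain** — cumulative DVHs at 0.02 Gy binning, D90%, D2cm3,
  V45Gy, V60Gy; prescription normalisation (CTV D90% → 30 Gy in 5 fractions);
  EQD2 conversion and cumulative plan-sums with a prior 45 Gy external-beam
  course; constraint checking against a shipped objective table; and the
  coverage-mitigation renormalisation that escalates the plan to the highest
  OAR-safe level.

The radiobiological core is the linear-quadratic equivalent dose in 2 Gy
fractions for *n* fractions of *d* Gy:

```
EQD2 = n·d·(1 + d/(α/β)) / (1 + 2/(α/β)),   α/β = 10 Gy (CTV), 3 Gy (OARs)
```

so the 30 Gy/5 fx boost prescription on top of 45 Gy/25 fx gives the CTV a
cumulative EQD2 objective of 40 + 44.25 = **84.25 Gy**, and the OAR boost
limits (bladder 23.75, rectum 17.0, sigmoid 19.5, bowel 17.0 Gy, D2cm3)
correspond to cumulative limits of 80/65/70/65 Gy.

## Worked example

```python
import rodplan as rp
from rodplan.cli import run_pipeline

phantom = rp.generate_phantom(rp.PhantomSpec(seed=7, ctv_volume_cm3=51.0,
                                             spacing_mm=2.5))
out = run_pipeline(phantom, rp.OptimizerConfig(strategy="SFRT_1", iterations=150))
m = out["report"].metrics
print(f"CTV   D90 = {m['CTV']['D90_gy']:.2f} Gy   V45 = {m['CTV']['V45_pct']:.1f} %")
print(f"CTV   cumulative EQD2(D90) = {m['CTV']['D90_eqd2_cum_gy']:.2f} Gy")
print(f"bladder D2cm3 = {m['bladder']['D2cm3_gy']:.2f} Gy")
```

prints

```
CTV   D90 = 30.00 Gy   V45 = 15.0 %
CTV   cumulative EQD2(D90) = 84.25 Gy
bladder D2cm3 = 0.29 Gy
```

D90 sits exactly on the prescription because the plan is renormalised to the
90% coverage level; V45 is the fraction of the CTV boosted past 150% of the
prescription by the rods; the bladder near-maximum stays far below its
23.75 Gy aim (the surrogate kernel has a much sharper fall-off than a real
arc delivery — see `docs/methods.md`). The same pipeline is available from
the shell:

```bash
rodplan phantom --seed 7 --out ph/
rodplan rods --structures ph/
rodplan optimize --structures ph/ --strategy SFRT_1 --out plan/
rodplan evaluate --structures ph/ --dose plan/dose.nii.gz --out report.json
rodplan cohort --n 5 --seed 42 --out cohort/
```

`evaluate` and `cohort` exit non-zero if any OAR hard limit is violated after
mitigation. Masks and dose travel as NIfTI; structures can also be exported
as a DICOM RT Structure Set.

## Layout

| module | contents |
| --- | --- |
| `rodplan.core` | `VoxelGrid`, `StructureMask`, `StructureSet`, `DoseGrid` |
| `rodplan.phantom` | seeded synthetic pelvic phantoms and cohorts |
| `rodplan.rods` | straight/bending rod generation, expansion, valley |
| `rodplan.optimizer` | surrogate peak-and-valley dose optimizer |
| `rodplan.dvh` | DVH curves, scalar metrics, normalisation, averaging |
| `rodplan.radiobiology` | EQD2, inverse EQD2, cumulative plan-sums |
| `rodplan.evaluation` | objectives, plan reports, mitigation, cohort stats |
| `rodplan.io`, `rodplan.cli` | NIfTI/DICOM/CSV/JSON I/O and the `rodplan` CLI |
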