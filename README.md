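# bystander-tgi

Simulation models for the **bystander-killing effect** of antibody-drug
conjugates (ADCs) and the **initial delay** of tumor growth inhibition.

ADCs deliver a cytotoxic payload (e.g. MMAE) into antigen-positive
(Ag+) tumor cells.  A membrane-permeable payload leaks back out and
enters neighbouring antigen-negative (Ag−) cells too — the
bystander-killing effect — so the efficacy of an ADC against a mixed
tumor depends on the Ag+ fraction β, the efflux-to-influx ratio
k = k_out/k_in, and the released dose C0.  This package is for
modellers in pharmacometrics / quantitative pharmacology who want a
tested, deterministic implementation of three coupled pieces:

1. **Payload exchange** between Ag+ cells, Ag− cells and the
   extracellular space — a closed linear three-compartment system

   dC_int,p/dt = β·k_in·C_ext − k_out·C_int,p
   dC_int,n/dt = (1−β)·k_in·C_ext − k_out·C_int,n
   dC_ext/dt = −k_in·C_ext + k_out·(C_int,p + C_int,n)

   solved both numerically and in closed form, with its equilibrium
   `(β·C0/(1+k), (1−β)·C0/(1+k), C0·k/(1+k))` and conservation
   structure exposed.

2. **Two-population tumor growth inhibition**: each subpopulation
   T1 = β·T0 (Ag+) and T2 = (1−β)·T0 (Ag−) is driven by *its own*
   payload concentration through an inhibitory Emax model,
   dT_i/dt = c·E(C_i)·F(T_i)·T_i − λ·T_i with
   E(c) = E0·(1 − Emax·c^γ/(IC50^γ + c^γ)) and F exponential or
   logistic.  Bystander killing switches off by setting k_out = 0
   (payload trapped in Ag+ cells).

3. **Erlang age-structured TGI**: drug-hit cells traverse n
   exponential stages (Erlang(n, θ) lag, mean n·θ) before dying, which
   turns the renewal equation
   dT/dt = ∫ c·ϕ(a)·E(t−a)·F(t−a)·T(t−a) da − λT into a linear chain
   of ODEs.  A direct quadrature solver for the renewal integral is
   included as an independent cross-check of the chain reduction.
   This reproduces the ~2-day delay between dosing and visible
   inhibition that memoryless TGI models cannot show.

## Worked example

```python
import numpy as np
from bystander_tgi import (
    AgeStructureParameters, DoseResponseParameters, PayloadParameters,
    TumorParameters, bystander_gap, critical_efflux_ratio,
    payload_equilibrium, simulate_age_structured, simulate_tgi,
)

p, dr, tu = PayloadParameters(), DoseResponseParameters(), TumorParameters()
grid = np.linspace(0, 60, 601)

eq = payload_equilibrium(p)          # k_in=1/d, k=2, beta=0.7, C0=200 nM
print(eq.c_int_p, eq.c_int_n, eq.c_ext_p)   # 46.67 20.0 133.33

on  = simulate_tgi(p, dr, tu, grid)                    # bystander on
off = simulate_tgi(p, dr, tu, grid, bystander=False)   # k_out forced to 0
gap = bystander_gap(on, off, tu.t0)
print(on["T_total"][-1], off["T_total"][-1])  # 1069.8 1529.3 mm^3 at day 60
print(grid[np.argmax(gap > 0)], gap[-1])      # 32.3 45.9

aged = simulate_age_structured(p, dr, tu, AgeStructureParameters(), grid)
i = np.argmax(aged["T_total"])
print(aged["T_total"][i], grid[i])            # 1036.8 at 1.6 days

print(critical_efflux_ratio(dr, p, tu.c, tu.lam))  # 3.2383
```

Reading the numbers: at the default mix (70% Ag+) the payload settles
at 46.7 nM in Ag+ cells, 20 nM in Ag− cells (66.7 nM intracellular in
total, i.e. C0/(1+k)).  Trapping the payload (`bystander=False`) kills
the Ag+ compartment harder but leaves the Ag− compartment untreated:
the permeable payload is *worse* for the first ~32 days and then wins,
ending 45.9 % of T0 ahead by day 60.  The age-structured model lets
the tumor keep growing to 1037 mm³ for ~1.6 days despite the 200 nM
dose before inhibition takes hold.  Finally, k̃ ≈ 3.24 is the efflux
ratio above which the equilibrium payload is too dilute to shrink the
tumor at all.

The same runs are available from the shell:

```bash
bystander-tgi payload --k-out 2 --beta 0.7 --out runs/
bystander-tgi tgi --bystander off --out runs/
bystander-tgi agetgi --n 20 --theta 0.1 --out runs/
bystander-tgi figure fig4 --out runs/fig4 --plot
bystander-tgi doseresponse eval --conc 0
```

Scenario files are YAML (see `bystander_tgi.scenario.ScenarioConfig`);
an empty file means "all defaults", unknown keys are rejected by name,
and identical configurations always produce byte-identical CSV output.

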