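# tocsim

Nash equilibria of the tragedy of the commons with heterogeneous investors.

`tocsim` is a small scientific Python package for studying what happens when
*N* selfish agents invest into a common-pool resource whose productivity
degrades with total exploitation. Agent *i* invests `x_i >= 0` at a per-unit
cost `c_i` and receives

```
E_i = r_i x_i P(x_tot) - c_i C_i(x_i),        x_tot = sum_j x_j,
```

where the productivity `P` satisfies `P(0) = 1`, `P' < 0` (exponential
`e^{-x_tot}`, power-law `(1+x_tot)^{-beta}`, or a finite commons
`1 - x_tot/x_max`), and the dimensionless cost function `C` is linear or
logarithmic, `C(x) = log(1 + gamma x)/gamma`, concave for `gamma > 0`.

Individual optimization couples all agents through `x_tot`: the Nash state
solves a self-consistency condition
`P(x_tot) - c_mean = -(x_tot/N) P'(x_tot)`. The package solves these states
in closed form (linear costs), by a bracketed scalar root solve or projected
gradient dynamics (curved costs), runs the iterated *decimation* of
unprofitable agents, and measures the emergent phenomena:

- a strictly **quadratic dispersion relation**
  `E(c_i) = (c_max - c_i)^2 / (-P')` with profitability threshold
  `c_max = P(x_tot)`;
- **catastrophic poverty**: typical payoffs scale as `1/N^2` (cooperating
  agents would get `1/N`);
- **oligarchs** — low-cost agents whose payoff stays finite as `N` grows;
- **runaway exploitation** for power-law productivity when `N >= beta` and
  costs vanish;
- for strongly concave costs (`gamma > 1`), **entry barriers** and
  saddle-node (`c_node = c_max (gamma+1)^2 / (4 gamma)`) **sudden-death
  market exits**.

## Worked example

```python
from tocsim import grid_population, decimate, dispersion_payoff

# 50 agents with c_i = 0.15 + 0.002 i, plus one oligarch at c = 0.1
pop = grid_population(0.15, 0.002, 50, oligarch_c=0.1)
res = decimate(pop)                       # iterated elimination
print(res.n_survivors)                    # 16
print(round(res.state.x_tot, 3))          # 1.719
print(round(res.state.c_max, 3))          # 0.179
print(round(float(dispersion_payoff(0.1, res.state.x_tot)), 3))  # 0.035
```

Sixteen agents survive (the oligarch plus the 15 cheapest bulk agents); total
investment settles at 1.719, so the commons' productivity — and with it the
profitability threshold — drops to 0.179. Every agent costlier than that has
been priced out. The oligarch earns 0.035, more than the whole surviving
bulk combined: the hallmark of catastrophic poverty.

The same from the command line:

```
tocsim reproduce table1 --out results/table1     # six benchmark equilibria
tocsim decimate --population pop.csv --gamma 0.5 --out results/run
tocsim bifurcation --gamma 1.5 --c-max 0.15 --out results/frozen
```

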