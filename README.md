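# colcomp — competition–colonization trade-off analysis for mapped forest plots

Do tree species that colonize vacant ground quickly survive poorly under
crowding, and vice versa? This package estimates both abilities per species
from standard forest-plot data — a mapped stem census with survival status,
and seed-trap counts — and tests the trade-off across species.

**Colonization ability** is `1/t`, the inverse of the expected number of
years until a species' seed first lands in a 10 × 10 m gap: a dispersal
kernel and a fecundity parameter are jointly estimated from seed-trap
counts by inverse modeling (Poisson likelihood, four kernel families
compared by AIC), the kernel is integrated over randomly placed gaps to get
the per-seed arrival probability `p_G`, and `1/t = p_G × F` with `F` the
annual seed output of a reference-size tree. **Competitive ability** is the
survival odds ratio (SOR) under intense crowding: a logistic regression of
survival on stem size and a neighborhood crowding index (distance-decayed
basal area of larger neighbors within 15 m), evaluated at the plot-wide
97.5th crowding percentile. Uncertainty comes from a seed-trap bootstrap
and a spatial 20 × 20 m quadrat bootstrap; the cross-species correlation
between `1/t` and SOR is tested with a paired bootstrap. A significant
negative correlation is evidence of a competition–colonization trade-off.

A full synthetic-community generator with known ground truth makes every
stage testable without field data. Model details, assumptions and
limitations: [docs/methods.md](docs/methods.md).

## Worked example

Generate a 13-species synthetic community, fit the seed shadow of one
species, and compute its colonization ability:

```python
from colcomp.synthetic import default_community_config, generate_community
from colcomp.seed_shadow import fit_all_families, select_best_kernel
from colcomp.colonization import colonization_ability

community = generate_community(default_community_config(), seed=7)
dataset = community.dataset
print(f"{len(dataset.trees)} stems, {len(dataset.traps)} traps, "
      f"{int(dataset.counts['count'].sum())} seeds")

fits = fit_all_families(dataset, "SP07")
best = select_best_kernel(fits)
print(f"best kernel: {best.kernel.family} {tuple(round(p, 3) for p in best.kernel.params)}")
print(f"beta = {best.beta:.3f} seeds/cm^2/yr, AIC = {best.aic:.1f}")

record = colonization_ability(best, dbh=10.0)
print(f"p_G = {record.p_gap:.5f}, 1/t = {record.inv_t:.3f} /yr, "
      f"t = {record.t:.2f} yr, LDD = {record.ldd:.4f}")
truth = community.ground_truth["species"]["SP07"]
print(f"truth: beta = {truth['beta']}, kernel = {truth['kernel']}")
```

Output:

```text
5080 stems, 149 traps, 7381 seeds
best kernel: lognormal (7.609, 0.516)
beta = 2.765 seeds/cm^2/yr, AIC = 207.4
p_G = 0.00029, 1/t = 0.062 /yr, t = 16.07 yr, LDD = 0.0001
truth: beta = 2.8, kernel = {'family': 'lognormal', 'params': [8.0, 0.6]}
```

The inverse model recovers the generating fecundity (2.765 vs 2.8) and
kernel (lognormal, median 7.6 m vs 8 m) from the trap counts alone.

The same workflow is available from the command line:

```bash
colcomp simulate --out data/ --seed 7
colcomp analyze --datadir data/ --min-seeds 50 --min-traps 10 \
    --n-boot 200 --out report.json
```

`simulate --paper-scale` switches from the desk-scale default (400 stems
per species) to full census density. `colcomp --help` lists the individual
stages (`fit-dispersal`, `abilities`, `fit-survival`, `sor`).

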