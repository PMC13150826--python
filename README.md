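# uvpdfy

Native mass spectrometry (nMS) combined with 193 nm ultraviolet
photodissociation (UVPD) can separate the coexisting conformers of an
intrinsically disordered protein by charge state and then read out, residue
by residue, how a bound metal ion changes each conformer's backbone.
`uvpdfy` is a tested, reusable implementation of that data analysis for
top-down practitioners: it takes deconvoluted per-scan fragment lists
(TopFD-style msalign or plain TSV) and centroided precursor peak tables,
and produces per-residue fragment yields, differential-yield statistics,
zinc-retaining (holo) fragment distributions, and Gaussian-mixture
conformer assignments. Human α-synuclein (UniProt P37840, 140 residues)
with Zn²⁺ is the bundled default system.

## What it computes

- **Theoretical fragment database** over the 12 UVPD ion series
  (a, a+1, a+2, b, c, x, x+1, y, y−1, y−2, z, z+1) × cleavage site × zinc
  count, with neutral monoisotopic masses from versioned element/residue
  tables. Zn adducts use Zn−2H (+61.913492 Da) by default, bare Zn
  selectable.
- **Matching and filtering**: each observed neutral mass is assigned within
  a relative tolerance of 2×10⁻⁶ (deterministic ambiguity resolution), a
  species is kept when seen in ≥16 of 20 scans per replicate and its
  isotope-envelope Pearson correlation exceeds 0.7.
- **Fragment yields**: after median normalization, the yield at site *i* is

  FY(i) = 100 · Σ I(a, a+1, a+2, x, x+1 at i) / Σ I(all kept species),

  and ΔFY(i) = mean FY(i)|Zn − mean FY(i)|apo is tested per site with a
  two-sample t-test (significant at P ≤ 0.001), summarized over the
  Nterm (1–60) / NAC (61–95) / Cterm (96–140) regions.
- **Holo fragments**: kept species retaining ≥1 Zn, collapsed to unique
  (terminus, site) pairs — same-terminus fragments at one site are one
  holo fragment — and counted per terminus.
- **Conformer assignment**: the charge-state distribution is fit with
  Σₖ Aₖ·exp(−(z−μₖ)²/2σₖ²) (k = 3, initialized at 7+/10+/13+);
  subpopulation fractions are normalized component areas, and per-charge
  zinc-stoichiometry profiles quantify how many metals each conformer
  binds.
- **Synthetic experiments**: a seeded generator plants ground truth for
  every stage (true FY vectors, changed sites, holo maps, CDS components)
  and writes the same file dialects the readers consume. Three presets
  emulate a compact, an intermediate and an extended conformer with
  distinct binding modes.

See `docs/methods.md` for conventions, noise model and design choices.

## Worked example

Simulate the compact ("low-charge", 7+) conformer preset and analyze it
end to end:

```python
import uvpdfy as u
from uvpdfy.pipeline import analyze_experiment, PipelineParams

cfg = u.make_conformer_presets(seed=1)["low-charge"]
sim = u.simulate_experiment(cfg)
res = analyze_experiment(sim.features, sim.precursor, cfg.sequence,
                         PipelineParams(max_zinc=cfg.max_zinc))
print(res.fy_results.summary())
print(res.cds["holo"].summary())
print("coverage (% of residues):", res.coverage)
print("holo fragments:", res.holo_counts)
```

prints

```
Differential UVPD fragment yields (holo - apo)
  sites tested: 139   significant (P<=0.001): 22
  mean dFY over significant sites: -1.74
     Nterm: -1.88
       NAC: -1.56
     Cterm: -1.51
Charge-state distribution Gaussian mixture
  components: 3   converged: True   residual norm: 5092
    center    sigma    amplitude  fraction
     6.980    1.176    3.946e+05    0.3820
    10.092    1.289    3.668e+05    0.3894
    13.143    1.144    2.427e+05    0.2286
coverage (% of residues): {'apo': 85.0, 'holo': 85.0}
holo fragments: {'Nterm': 6, 'Cterm': 31, 'Sum': 37}
```

Reading it: 22 of 139 backbone sites show a significant yield drop after
Zn incubation, averaging −1.74 percentage points — strongest in the
N-terminal region — i.e. the compact conformer's backbone is protected by
binding. The precursor charge-state distribution decomposes into three
Gaussian subpopulations centered at 7+, 10+ and 13+. Only 6 N-terminal-
series holo fragments survive against 31 C-terminal ones, the signature of
C-terminal electrostatic binding in this preset. Sequence coverage is
85.00 % of the 140 residues.

The same analysis runs from files: `uvpdfy simulate` writes an experiment
to disk, `uvpdfy run` executes a JSON-configured pipeline, and
`uvpdfy run-preset --preset low-charge out/` does both in one step,
emitting evidence tables, FY/ΔFY tables, region summaries, holo counts,
CDS components and a run manifest. `uvpdfy db`, `uvpdfy cds` expose the
individual stages.

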