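# Methods

`fracture-clock` turns a tabulated timetable of histological fracture-repair
features in infants (≤ 12 months) into a reproducible inference engine for
the age of a fracture at death. This note records the model, the encoding
conventions, the numerical choices, and what the synthetic validation does
and does not demonstrate.

## The timetable model

Fourteen histological features are tracked, in the order a pathologist
assesses them: haemorrhage, fibrin strands, polymorph infiltrate, macrophage
infiltrate, granulation tissue, osteocyte loss, osteoclasis, mesenchymal
condensation, early woven osteoid, distinct bony trabeculae and cartilage
nodules, calcification, fracture union, lamellar bone deposition, and
restoration of normal bone structure.

Each feature carries up to four landmarks, all in hours since the fracturing
event (days are stored as `24·d`):

| landmark | meaning |
|---|---|
| `t_first` | earliest observed appearance |
| `t_all_on` | age from which the feature is present in *all* fractures |
| `t_all_off` | end of the universal-presence window |
| `t_last` | latest age at which the feature may still be seen |

with `t_first ≤ t_all_on ≤ t_all_off ≤ t_last` where defined. The hard
constraint semantics are:

* **present** → age ∈ `[t_first, t_last)`;
* **absent** → the fracture has either not reached, or has passed, the
  window of universal presence: age ∈ `[0, t_all_on) ∪ [t_all_off, ∞)`
  (undefined landmarks drop their branch; a feature that is never universal
  yields no constraint from absence);
* **unknown** observations, and *advisory* features (macrophage infiltrate,
  which adds little to ageing), never constrain.

Constraints are intersected exactly over a small algebra of finite unions of
half-open hour intervals `[lo, hi)` (`+∞` allowed only as an upper
endpoint). Half-open intervals make merge semantics unambiguous; all default
landmarks are integer hours, so no floating-point edge tolerance is needed.
The final feasible set is clipped to the 92-day horizon (2208 h) beyond
which bone structure is restored and differential ageing becomes difficult.

### Transcription conventions for the default knowledge base

* "universally seen **by** N days" → `t_all_on = 24·N`.
* "in all **by A–B days**" → universal onset at the conservative upper end
  `B`; the lower end `A` is retained in the prevalence profile as the start
  of the `all` category (calcification: all by 22–28 d → `t_all_on = 672 h`,
  profile `all` from 528 h).
* "occurred **by A–B days**, increasing…" for a first appearance →
  `t_first = 24·A` (trabeculae/cartilage: 8–14 d → `t_first = 192 h`).
* Under-specified disappearance or onset times ("thereafter disappearing",
  "short-lived") are encoded once as explicit defaults and flagged
  `inferred_defaults` in the KB file, so they are auditable and overridable:
  fibrin `t_first = 2 h`, `t_all_off = 72 h`, `t_last = 168 h` (still
  visible on the fracture surface at 3 days); polymorphs `t_first = 12 h`,
  `t_all_off = 48 h`, `t_last = 96 h`; granulation tissue and mesenchymal
  condensation `t_first = 72 h`, `t_all_on = 120 h` (periosteal
  proliferation visible at 3 days, established by the time woven osteoid is
  universal); woven osteoid `t_first = 96 h` (early osteoid at 4 days);
  fracture union `t_first = 504 h` (bridging begins as trabecular callus
  matures, all bridged by 28 d); osteocyte loss `t_all_on = 168 h`
  (complete loss described at 7 days).
* Metaphyseal fractures: only cortical osteoclasis is earlier
  (`t_first = 24 h`, `t_all_on = 36 h`); all other features use the generic
  timelines because bone healing at the metaphyseal periphery is identical
  to bone elsewhere. Context overrides drop any explicit prevalence profile
  and fall back to the landmark-derived one, so the override is coherent.
* Restoration is modelled as a feature with `t_first = t_all_on = 2208 h`;
  recording it present yields the *beyond-horizon* verdict and suppresses a
  numeric range rather than returning an empty set.

The default time axis is the union of all landmark hours — 19 bins from
`[0,1)` to `[864,2208)` — the finest partition on which every default
prevalence profile is piecewise constant (verified by a test).

## Posterior over age bins

The timetable's per-age proportions are coarse categories — `none`,
`minority`, `majority`, `all` — mapped to probabilities
`0.02 / 0.30 / 0.80 / 0.98` by default. The exact proportions behind the
original table are not published; these values are configurable per KB file
and deliberately bounded away from 0 and 1 so that a single observation can
never zero the posterior. For feature *f* and bin *b* (evaluated at the bin
midpoint), `p_f(b)` is the mapped category probability; the likelihood of a
case is `∏ p_f(b)` over present and `∏ (1 − p_f(b))` over absent
constraint-grade observations — the same observation set the hard
constraints use, so the two routes are directly comparable. Advisory
features contribute to neither. Priors: uniform over bins (default) or
uniform in log-time, `w_b ∝ ln((hi_b + 1)/(lo_b + 1))`, offered because the
axis spans 1 h to 92 d. The credible set is the smallest set of bins
reaching 95% posterior mass (configurable), ties resolved toward earlier
bins for determinism.

**Limit agreement.** The posterior reproduces the hard constraints when the
category map is pushed to its logical limit. That limit is *not*
`{ε, 1−ε}` on all four categories: presence is impossible only where
prevalence is `none`, and absence only where it is `all`, so the faithful
map is `none → ε`, `all → 1 − ε`, `minority = majority = ½`. Under that map
the 95% credible set always falls inside the span of the feasible set
(property-tested); pushing `minority → ε` instead would wrongly annihilate
ages where a feature is genuinely present in only a minority of fractures.

## Verdicts

* **Ante-/post-mortem** — ante-mortem iff osteocyte loss (never seen in
  post-mortem fractures) or haemorrhage is present in any region, with
  haemorrhage redefined to include significant medullary or periosteal
  haemorrhage with or without red cells in the cortical fracture line
  (red cells can be lost during processing, so haemorrhage absence is
  given no age constraint and its prevalence never exceeds `majority`).
  Absence of both markers is *indeterminate*, never "post-mortem".
* **Mobile fracture sites** show mixed-age reactions from recurrent motion;
  when `mobile` is flagged, only observations from the periosteal reaction
  away from the fracture line keep constraint grade.
* **Cartilage-only** growth-plate fractures show no repair features and are
  reported *not ageable*; a case recording a bone feature present in the
  fracture line of such a fracture is rejected at validation.

## Multi-event detection

Present-state constraint-grade features are partitioned into the minimal
number of groups whose intersected age sets are non-empty. Consistency is
monotone under subsets, so an exact subset dynamic programme (over at most
`2^14` feature masks) finds the minimal count; among minimal partitions the
tie-break maximizes the overlap between each group's feasible-span and its
members' individual constraints, then takes the lexicographically least
grouping, so results are deterministic. A refracture line passing
completely through existing callus indicates a second, later event and
forces at least two groups even when the features are mutually consistent;
if fewer than two evidenced groups exist, the younger event is reported as
an unevidenced group with the full age range. Groups are returned oldest
first. Fractures from the same infant are compared pairwise:
*distinguishably different* iff their feasible sets are disjoint.

## Synthetic cohorts

The simulator emulates the study population the timetable was built from:
52 infants, ≈169 fractures in expectation (zero-truncated Poisson per
infant with mean 169/52), infant ages log-normal truncated to 3 weeks–11.9
months with median ≈4.1 months (σ_log = 0.55 reproduces the published
range at n = 52 and leaves about two-thirds of infants under 6 months),
sex ratio 28:24. True fracture ages are log-uniform on `[1 h, 2208 h)` —
the published cohort spans hours to months but gives no age histogram, and
log-uniform weights every decade of the clock equally. Healing-rate
variation between infants is a per-infant log-normal factor (median 1,
σ = 0.2 by default; the source reports the existence, not the magnitude,
of this variation) applied as time dilation: features are sampled at
effective age `true_age / factor`, which keeps fractures within one infant
consistent. Feature states are Bernoulli draws from the KB prevalence
probabilities; each observation is independently set to `unknown` with
probability 0.1 to emulate unassessable slides (a synthetic-only mechanism,
not a documented property of the source data). Refractures are simulated
as a morphological flag only — the truth table carries one true age per
case and observation mixing from two events is not simulated.

With rate variation off and probabilities clamped to {0, 1} (present iff
the category is `majority`/`all`), recovery is exact by construction:
feasible-set coverage of the true age is 1.0 over ~2000 simulated
fractures, and this is asserted as an exact property, not a statistical
one. With noise, credible-set coverage degrades monotonically in the rate
σ (tested at σ ∈ {0, 0.1, 0.3}).

What passing these tests shows: the engine inverts its own generative
model exactly, and degrades gracefully under the modelled biological
variation. What it does not show: performance on real histology, where
feature recognition error, within-infant heterogeneity, co-occurring bone
disease (excluded from the source data histologically) and non-tabulated
features all exist.

## Known limitations

* Hour-resolution landmarks inherit the precision of the published text;
  the original graphic table's exact bin edges and colour cut-offs are not
  recoverable, so category probabilities are engine defaults.
* The 95% credible mass is an engine choice; the source claims a "high
  degree of certainty" without quantifying it.
* Mixed-age reactions at mobile sites versus true refracture are reported
  (partition plus caveat codes) but not adjudicated — that judgement
  remains with the pathologist.
* Problem sizes in the test-suite (cohorts of a few hundred infants,
  2×10⁴ randomized algebra checks, exhaustive partition enumeration up to
  8 features) were chosen to exercise every code path at desk scale.
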