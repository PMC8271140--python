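# Methods

This note documents the models and procedures implemented in `phyloconv`,
the choices made where the design was genuinely open, and what the
synthetic-data experiments do and do not demonstrate.

## Characters on a tree

All analyses share one coordinate system: a rooted phylogeny with strictly
positive branch lengths (zero or missing lengths are replaced by a
configurable ε = 1e-6 so transition probabilities stay defined). A branch
is identified by its child node. Internal nodes without labels are named
`N<postorder index>` deterministically.

Character evolution is modelled by reversible continuous-time Markov
chains. Amino acid models are assembled as `Q[i,j] = s[i,j]·π[j]` from a
symmetric exchangeability matrix and stationary frequencies, and rescaled
to one expected substitution per unit branch length; the default is the LG
exchangeability matrix (Le & Gascuel 2008, shipped as `data/lg.dat` in
PAML layout) combined with alignment-wide observed frequencies (pseudocount
0.5). Any PAML-format matrix (e.g. mtVer) can be substituted via
`SubstitutionModel.from_paml`. The binary phenotype uses a two-state chain
with separate gain and loss rates in the tree's own branch-length units
(not rescaled).

Likelihoods are computed by Felsenstein pruning with per-node scaling;
marginal ancestral posteriors by the standard two-pass (inside/outside)
algorithm. Both are validated against joint enumeration over all internal
state assignments on small trees (tolerance 1e-8). MAP states are the
posterior argmax with ties broken toward the lowest alphabet index
(PAML amino acid order), so reconstructions are deterministic. `X` is
treated as fully missing data (all-ones partial likelihood); how rarer
ambiguity codes should be handled is left to the caller (they are rejected
at parse time).

**Rate handling.** One substitution-rate multiplier, shared by all sites of
an alignment, is fitted by maximum likelihood (bounded scalar search on the
log scale) and used for reconstruction. Per-site ML rate scaling was
considered and rejected as the default: the downstream scores consume only
MAP state changes, and the null calibration conditions on the *empirical*
per-site substitution counts, so a site-level rate misfit perturbs the
observed and the null score distributions together. Gamma-mixture rates are
not implemented; the shared multiplier is the single tuning point.

The phenotype is reconstructed under the fitted gain/loss chain with an
equal-prior root (the trait's ancestral state is not assumed known at
reconstruction time). If the rate optimiser hits its bounds
[1e-6, 100] a warning is logged; this is common and benign when one
direction of change is absent from the data (the rate is then effectively
zero).

## Simultaneous scores

A branch event is a branch whose parent and child MAP states differ; a
branch carries at most one event per character, and a reconstructed
multi-step change (parent X, child Z) counts as the single event X→Z.
Given the phenotype events and one site's amino acid events:

* **Convergence** = #branches with a phenotype gain (0→1) and an amino
  acid event ending in the foreground residue;
* **GWAS** = Convergence's gains term + #branches with a phenotype loss
  (1→0) and an amino acid event *starting* from the foreground residue
  (the same foreground residue for both terms);
* **All changes** = #branches with any phenotype event and any amino acid
  event.

Because no foreground residue is known a priori, the per-site score for
Convergence and GWAS is the maximum over all residues observed in the
site's events (ties toward the lowest alphabet index). The three scores
are nested per site: Convergence ≤ GWAS ≤ All changes. The foreground
*phenotype* polarity is fixed by the user and never auto-flipped.

## Null calibration

The null keeps the tree and the reconstructed phenotype events fixed and
re-draws genotype events only:

1. a substitution count k is drawn from the empirical histogram of per-site
   reconstructed event counts;
2. k distinct branches are chosen with probability proportional to branch
   length (weighted sampling without replacement via exponential keys);
3. event states follow a random walk over the 20 amino acids along the
   chosen branches in preorder — each step moves to one of the other 19
   residues uniformly, so every event is a real change;
4. the null site is scored with the identical best-foreground maximisation
   used on real sites.

Step 3 is a declared design choice: the score only inspects event
from/to states on phenotype branches, and under the maximisation over
foreground residues the walk's uniform marginals are the natural
uninformative choice. Placement proportional to branch length matches the
leading-order probability of a substitution on a branch under any clock-free
CTMC.

Thresholds: the significance threshold is the smallest integer score s with
null tail probability P(score ≥ s) ≤ α/n_sites (Correction 1) or
α/(3·n_sites) (Correction 2; 3 = number of test types). With the default
100,000 null sites per run, corrected levels below 1e-5 are beyond
Monte-Carlo resolution; the threshold is then set one past the observed
null support and flagged `resolution_limited`. Discreteness of the score
makes the procedure conservative: measured familywise error on fully null
synthetic data is well below the nominal 0.05 (see
`scripts/acceptance.py`).

## Profile change

Per site, the model space is a finite library of amino acid propensity
profiles. Under the **no-change** model one library profile supplies the
stationary frequencies of a CAT-style model (uniform exchangeabilities by
default) on every branch; under the **change** model the foreground and
background branch classes carry two different profiles (ordered pairs,
fg ≠ bg). Branch classes come from the reconstructed phenotype: a branch is
foreground iff its child's MAP phenotype is 1, so a branch on which the
phenotype changes is classified by its child state; the root draws from the
profile of its own reconstructed class. With equal prior odds between the
model classes and the library's prior weights within each class, the
reported score is the posterior probability of the change model. A per-site
rate is fitted by ML under the no-change model and then held fixed for both
models, so rate variation is not mistaken for profile change.

The shipped library (`data/profiles_c10_like_synthetic.tsv`) is a
**synthetic stand-in**: ten fixed, data-independent profiles built from
physicochemical residue groupings (85% of the mass uniform within the
group), playing the role of a CAT-C10-style category set without being the
published estimates. Any library can be supplied; posteriors are invariant
to profile relabelling, and a single-profile library yields posterior 0 by
construction. A profile with zero mass on an observed residue drives the
site's log-likelihood to a floor value (−1e6) rather than −∞, with a
warning.

The quadrant cross-test dichotomises sites at a simultaneous-score cutoff
(default: half the maximum observed score, rounded up — mid-range on the
discrete scale; always reported alongside the result) and at posterior 0.5,
and applies a two-sided Fisher exact test to the 2×2 table. Tables with an
empty row or column return p = 1 with a warning.

## Synthetic data

The generator emulates the shape of a multi-species mitochondrial protein
study. Defaults: 200 extant tips from a pure-birth tree (rate 1; expected
tree length ≈ n−1), a binary phenotype simulated as an exact two-state CTMC
(gain = loss = 0.035 per unit length, ancestrally absent) rejection-sampled
until the number of independent origins — branches with a net 0→1 change —
hits the target (default exactly 7, mirroring a moderately recurrent
trait); 2,000 sites (a typical concatenated gene-set size) under LG with
gamma(0.5) site-rate multipliers scaled so an average site expects 2
substitutions over the whole tree, and 5% hypervariable sites at 10× rate.
Amino acid sites are simulated by uniformisation (exact jump chains), so
every true substitution is recorded; branch-resolution "net" events are
what reconstruction can recover and what the ledger accounts.

Planted sites overwrite simulated history rather than biasing rates, so
ground truth is unambiguous: a *convergent* plant overwrites the descendant
clade of each phenotype-gain branch (with probability `p_couple` per gain)
with the foreground residue, recording the realised, non-shadowed event
count; a *profile-change* plant re-simulates the site with class-dependent
profiles switching at branch resolution.

What the generator does **not** emulate: codon structure and selection,
indels/alignment error, mtDNA compositional bias, tree estimation error
(the true tree is given to the pipeline), and correlated rate variation
across branches. Passing calibration and power tests therefore demonstrate
the statistical machinery's correctness under its own assumptions, not
robustness to misspecified trees or alignments.

## Experiment sizes

The packaged experiments use desk-scale problem sizes chosen to keep Monte
Carlo error small while remaining quick on one CPU: familywise-error
calibration uses 200 null replicates of a 200-tip × 500-site dataset with
100,000 null sites each (binomial SE ≈ 0.015 at a true rate of 0.05);
planted-site power uses 50 replicates; profile-change recovery uses 100
planted sites across 10 datasets; the quadrant-test calibration uses 1,000
replicates of 500 independent pairs. The familywise-error experiment scores
the Convergence approach, whose threshold is the tightest of the three.

## Known limitations

* Events are called on hard MAP states; reconstruction uncertainty is not
  propagated into the scores (posterior-weighted event calling would be the
  natural extension).
* The profile-change model simplifies one-change-event modelling on
  transition branches down to the two-class partition; transition branches
  are classified by child state.
* The empirical substitutions-per-site histogram is taken from the same
  reconstruction that produces the observed scores; both therefore share
  any reconstruction bias, which is what keeps the calibration honest but
  also means the null is conditional, not absolute.
* Score ties between candidate foreground residues are broken
  deterministically by alphabet order, which can matter for reporting (not
  for the score value).
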