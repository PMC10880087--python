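# Methods

## Problem and scope

`pcfkit` estimates per-kilogram product carbon footprints (PCF, kg
CO₂-equiv/kg) of pure organic chemicals from molecular structure alone.
The package covers the modeling workflow — curation, featurization, the
atom-bond transformer, classical baselines, hyperparameter search, metrics,
applicability domain, and attention attribution — but not the life-cycle
accounting that produces PCF labels in the first place (database retrieval,
allocation, energy harmonization; for reference, the chemical-industry
electricity and heat factors used in such harmonizations are about 0.16 and
0.071 kg CO₂-equiv per MJ). Those steps need licensed inventory databases
and are out of scope.

## Curation rules

A record survives curation iff its SMILES parses; purity is at least 0.80
or unset; no metal atoms are present; it is a single covalent unit (no
dot-separated components); at least one carbon is bonded to hydrogen or to
another carbon (the operational "organic" test — CO₂, carbonates and bare
salts fail it); and it carries no wildcard/repeat-unit atoms (polymers).
Each exclusion is logged with a rule id (`parse_failure`, `low_purity`,
`metal`, `mixture`, `inorganic`, `polymer`). Duplicate molecules are merged
by canonical SMILES with unweighted mean PCF. Two different metal policies
are deliberate: *training* curation excludes metal-containing records
outright, while *inventory* normalization for applicability-domain
screening strips detachable metal counterions and keeps the organic
component, dropping only pure salts, multi-organic mixtures, polymers and
inorganics.

The 0.80 purity bound is treated as a generic fraction (mass vs mole is
immaterial to the rule's implementation).

## Featurization

Atoms: one-hot blocks for element (C, N, O, S, P, F, Cl, Br, I, B, Si,
other), degree (0–5, ≥6), chirality tag, hybridization (sp…sp³d², other),
attached hydrogens (0–4, ≥5) and aromaticity. Bonds: order
(single/double/triple/aromatic), stereo tag, conjugation, ring membership.
Flags are encoded as two-state one-hot blocks so *every* block sums to
exactly one. Feature dimensions: 37 per atom, 14 per directed bond.

Interatomic matrices: adjacency; topological distance (shortest-path bond
counts — chosen over geometric distances because it needs no conformer and
is deterministic); and a Coulomb matrix M_ii = 0.5·Z_i^2.4,
M_ij = Z_i·Z_j/r_ij over heavy atoms. By default r_ij is the topological
distance × 1.5 Å (a deterministic surrogate bond length); a seeded 3-D
conformer mode (`embedded3d`) is available and falls back to the surrogate
with a warning when embedding fails.

Descriptors: the 210 two-dimensional physicochemical and fragment-count
descriptors shipped with RDKit, in an order frozen by a packaged manifest
(`descriptor_manifest_v1`); non-finite values are imputed to 0 with a log
entry. Descriptors are standardized with training-set mean and standard
deviation inside the trained model. Fingerprints: ECFP4 (radius 2, 2048
bits), RDKit path fingerprint (2048 bits), MACCS keys (167 bits).

Featurization preserves the input SMILES atom order (no internal
canonicalization), which makes permutation covariance a testable property
rather than a vacuous one.

## The atom-bond transformer

Architecture constants: 6 attention heads, one encoder and one decoder
block, feed-forward expansion ×4, post-norm residual blocks, no positional
encodings anywhere (this is what guarantees predictions are invariant under
atom reordering). The per-head width is `hidden_dim // 6` with the output
projection mapping back to `hidden_dim`, so the hidden width need not be a
multiple of six — the tuning lattice runs over multiples of 50.

Message passing uses directed bonds; the reverse bond is excluded from a
bond's aggregation set. Bond "surrounding substructure" information enters
through the conjugation and ring flags. Atom states are sums of incoming
bond hidden states plus a learned projection of the raw atom features (so
bond-free molecules like methane are still representable). Decoder
attention logits receive the additive bias λ·(A + s(D) + s(C)) with
per-molecule min–max scaling s to [0,1]; λ = 0 recovers unbiased
attention exactly. Pooling is the arithmetic mean over atoms (scale-stable
across molecule sizes, unlike a sum). The pooled embedding is concatenated
with the standardized descriptor vector and passed through one hidden
feed-forward layer to the scalar output.

Training: Adam on mean-squared error on the raw PCF scale (a log1p switch
exists but is off by default), batch size 32, learning rate 1e-3, fully
seeded (initialization, shuffling, dropout). Molecules are processed as
padded mini-batches; padded keys are masked out of every softmax with an
additive −10⁹ and padded atoms out of the pooling, so batching never
changes any molecule's value (verified to machine precision). Batches are
assembled by a seeded "bucketed shuffle" — random permutation followed by a
stable sort on bond count — which keeps padding small while still mixing
equal-sized molecules across epochs. The epoch with the lowest validation
RMSE is kept; early stopping uses a configurable patience (default 50
epochs). A non-finite loss aborts with an error naming the epoch.

The whole network runs on `pcfkit._autodiff`, a ~300-line reverse-mode
autodiff over NumPy float64 arrays written for this package; its gradients
are tested against central finite differences through the full model.

Bond self-attention attends over all bond pairs by default; a
`masked_bond_attention` flag restricts attention to bonds sharing an atom.
Checkpoints are a zip archive of a JSON header (config, manifest version,
training history) plus exact float64 weights; save→load round-trips
bit-exactly.

## Attribution

Decoder attention maps are row-stochastic over atoms. An atom's raw weight
is the attention it *receives* — the column mean — averaged over decoder
blocks and heads, renormalized to sum to one ("emitted" and max-aggregation
variants are available behind flags). Substructure shares are sums of atom
weights over user-supplied atom sets; shares of any partition sum to one by
construction. Renderings shade atoms on a per-molecule green→red ramp
(relative, not cross-molecule calibrated — absolute anchoring would need a
calibration the method does not define) and write a JSON sidecar with the
weights and ramp anchors. Atom-to-precursor mappings for raw-material
attribution are user-supplied; automated reaction atom-mapping is out of
scope.

## Baselines

Nine models: {ANN, RF, SVM} × {MACCS, PATH, ECFP4}, each tuned by 5-fold
grid search on cross-validated RMSE (ties keep the earlier grid point) and
refit on the full training set. Grids are intentionally small:
RF {100, 300 trees} × {depth ∞, 10} with sqrt-feature subsampling (the
standard choice for 2048-bit fingerprints); SVM (RBF) {C 1, 10, 100} ×
{ε 0.1, 0.5}; ANN one hidden layer of 100 units × {L2 1e-4, 1e-2}, Adam,
300 iterations. These grids are pragmatic defaults, not a reproduction of
any published tuning protocol.

## Applicability domain

Binary 2048-bit ECFP4; Euclidean distance (√Hamming for bit vectors); k = 5
neighbors; threshold T = Ȳ + Z·σ with Z = 0.5, where Ȳ and σ are the mean
and *population* (divisor n, configurable) standard deviation of each
training molecule's mean distance to its k nearest *other* training
molecules. Self-matches are excluded when fitting — otherwise duplicated
training molecules collapse Ȳ to zero. A query exactly at T counts as
inside (only distances strictly above the threshold are outside). All
neighbor searches are exact all-pairs computations; no approximate index is
used.

## Hyperparameter search

Gaussian-process surrogate (Matérn 5/2, inputs scaled to the unit cube,
normalized outputs) with expected-improvement acquisition over the discrete
lattice; candidates are fresh random lattice samples plus the one-step
neighborhood of the incumbent, deduplicated against evaluated points, so
proposals are always on-lattice. Default budget 30 with 10 seeded random
initial points — ample for a smooth objective on a 4-D lattice. A config
whose objective raises is scored +∞ and logged; the search continues. The
optimization criterion is validation RMSE.

## Synthetic ground truth

The generator assembles molecules from a seeded grammar: substituted
aromatic and saturated rings (benzene, pyridine, furan, thiophene,
cyclohexane, piperidine, piperazine), functionalized alkyl chains, and an
ester-rich "heavy" family (terephthalate/glycol/adipate diesters, glycerol
triester). Targets follow an additive group-contribution model
target = base + Σ_f c_f · count(f) + ε with ε ~ N(0, σ²) (clipped at
0.01). The default fragment table makes the ester carbonyl the
PCF-intensive fragment (3.6 kg CO₂-equiv/kg per occurrence vs 0.3–1.5 for
amide, nitrile, amine, halogen, aromatic ring, hydroxyl, ether; base 1.0);
with the default 20% heavy-tail fraction roughly a fifth of generated
records exceed 8 kg CO₂-equiv/kg, mirroring the long right tail of curated
industry PCF data. Default study conditions: 600 generated records, noise
standard deviation 0.3.

What the generator does *not* emulate: supply-chain variability (feedstock
routes, purification trains, regional energy mixes), heteroscedastic or
structured noise, and molecules beyond its grammar (fused polycycles,
stereo-rich natural products, organometallics). Passing tests on this data
therefore demonstrate that the pipeline can recover additive substructure
signal under realistic noise — not that any accuracy level transfers to
real PCF data.

Because the ground truth is linear in fragment counts, ordinary least
squares on the *true* counts is the recoverability oracle: its residual
RMSE is the noise floor that bounds any structural model, and its
coefficient recovery (within three standard errors at the default study
size) certifies the generator's identifiability.

## Study sizes and numerical choices

The test bench trains the reference model (hidden width 200, three
message-passing rounds) on the 600-record study — about 270 unique
training molecules after merging — for up to 40 epochs with patience 12;
the attribution study uses a graph-only model (no descriptors, hidden width
100) so that attention must carry the structural signal rather than riding
on fragment-count descriptors. These sizes were chosen as the smallest
study at which the ground-truth oracle is comfortably identifiable.
Tolerances: attention row sums and permutation invariance to 1e-5
(float64 accumulation-order effects only); oracle equivalences to 1e-12;
checkpoint round-trips bit-exact. Degenerate inputs: single-atom molecules
skip the bond pathway; constant interatomic matrices min–max scale to zero;
zero-variance descriptor columns get unit scale.

## Known limitations

- Attention attribution is a *relative* saliency signal; it is validated
  here against additive synthetic ground truth, not against measured
  raw-material footprints.
- The applicability domain uses fingerprint geometry only; it cannot flag
  chemicals whose *process* (not structure) is atypical.
- Training is CPU-bound NumPy; practical up to a few thousand molecules and
  hidden widths of a few hundred, not a large-scale training stack.
- PCF labels in reality vary with synthesis route and region; a
  structure-only model cannot resolve that variability.
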