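# Methods

## Template-based SMILES

The premise of the whole package is that string similarity between SMILES
is only meaningful when equivalent substructures are written identically.
General-purpose SMILES writers guarantee canonical *molecules*, not
consistent *substrings*, so `lipidlux` renders every species itself from
fixed class templates.

Chains are described by `ChainSpec(carbons, double_bonds, hydroxyls,
role)`. Positions count from the carbon attached to the head group or
carbonyl (position 1); a double bond at `d` sits between carbons `d` and
`d+1`. An acyl fragment is written carbonyl-first: `C(=O)` then carbons
2..n as `C`, with `(O)` immediately after a hydroxyl-bearing carbon and
`=` before carbon `d+1`. Validation rejects chemically impossible specs
(hydroxyl on the carbonyl carbon, positions out of range, cumulated
double bonds centred on a substituted carbon, which would need a
pentavalent carbon).

Class templates:

* **Ceramide family** (CER, IPC, MIPC, MIP2C): the sphingoid base is
  written from its methyl end down to carbon 2, with the 1,3-dihydroxy
  2-amino backbone fixed by the template (`...C(O)C(CO)N...`); the C1
  oxygen carries either a free hydroxyl (CER) or a phosphoinositol /
  mannosyl-phosphoinositol head. The base is saturated by default
  (d-series); extra hydroxyls (t-series, position ≥ 4) and double bonds
  (position ≥ 4) are supported.
* **Glycerophospholipids** (PC, PE, PS, PI, PA):
  `C(COC(=O){sn1})(OC(=O){sn2})COP(=O)(O){head}` with fixed head
  fragments. The choline nitrogen is written charge-free (`N(C)(C)C`),
  matching the sanitization convention; the formula code accepts this
  single hypervalent-as-written case.
* **Glycerolipids** (TAG, DAG) analogously without the phosphate.
* **Sterols** (STEROL, CE): a fixed ergostane-type core (Δ5,7,22 triene,
  24-methyl side chain; C28H44O) with the 3-O free or esterified.

Every template was validated by parsing the rendered string and checking
the implicit-hydrogen formula against both a closed-form per-class
composition and RDKit (see `tests/test_lipid_model.py`). Note that the
saturated d16:0/18:0;OH(2) ceramide is C34H69NO4 — an odd hydrogen count
is forced by valence for any acyclic C34 N1 molecule with one C=O; an
even count sometimes quoted for this composition is not reachable.

Sanitization strips chirality (`@`), cis/trans (`/`, `\`) and charge
decorations, collapsing bracket atoms whose remaining content is a bare
element (`[N+]` → `N`). It is idempotent.

`simplify_terminal_branches` removes parentheses around branches written
last at their nesting level (`...CCC(O)` → `...CCCO`). The template
renderer deliberately keeps such parentheses so a hydroxyl is *always*
spelled `(O)`; the simplifier produces the form conventional SMILES
emitters output. This distinction is invisible to graph-based methods
but changes substring profiles — see LINGO below.

## Similarity metrics

All four metrics return distances in [0,1] and satisfy d(a,a)=0 and
symmetry.

* **Levenshtein** (default): unit-cost edit distance divided by the
  longer string length. Normalization by `max(|a|,|b|)` keeps the value
  in [0,1]; the unnormalized distance is a true metric (triangle
  inequality is property-tested). Implemented as a row-wise DP with a
  prefix-minimum scan for the in-row insertion dependency; verified
  against naive recursion and edlib.
* **Smith–Waterman**: local alignment with match +1, mismatch −1, linear
  gap −1 (configurable); distance `1 − S/max(|a|,|b|)`. The parameters
  are a package choice — local alignment of lipid strings is mainly
  included to demonstrate its failure mode: terminal features (e.g. an
  end-of-chain hydroxyl) fall outside the optimal local span and are
  silently ignored.
* **LINGO**: Tanimoto over overlapping 4-character substrings after
  mapping ring-closure digits to `0`. Two variants: count-based
  (integral Tanimoto, `sum(min)/sum(max)`, the default) and binary
  (presence/absence).
* **Path fingerprint** (`fp2`): all simple linear paths of 1–7 atoms in
  the parsed heavy-atom graph, canonicalized by taking the
  lexicographically smaller direction of the (element, bond-order) token
  string; single-atom C/N/O paths are excluded; each path is hashed
  (FNV-1a) into 1021 bits. Zero-distance pair counts depend only on
  path-set identity, not the hash width.

On the 17-ceramide hydroxyl scan the edit distance separates all
isomers, ranks each molecule's nearest isomers strictly by hydroxyl
offset (one-carbon shift = 2 edits, two = 4, three or more = 6, hence
the 6/48 = 0.125 plateau printed as 0.12), while the substring metrics
collapse large cliques of isomers to distance zero.

**LINGO zero-pair convention.** The number of isomer pairs LINGO scores
as identical is sensitive to exactly how the strings are written at
chain termini. On the fully parenthesized template strings the
count-based variant leaves a 12-isomer clique (66 pairs) and the binary
variant a 15-isomer clique (105 pairs). On conventionally written
strings (redundant terminal parentheses elided, so the 18-hydroxyl
isomer ends `...CCCO`), the binary variant leaves a 14-isomer clique —
91 pairs, the published benchmark figure. The benchmark reproduction
therefore evaluates the binary variant on terminal-simplified strings;
both variants remain available on any input. The same elision would also
shrink the edit distance of the terminal isomer (4 edits instead of 6),
which is why the renderer itself keeps full parentheses.

## Chemical space

Molecule *i*'s descriptor is row *i* of the distance matrix, i.e. its
distances to all members of the set — an (n−1)-dimensional coordinate
system by construction. Rows are column-centered (no unit-variance
scaling: the descriptors share a scale) and projected by PCA; each
axis's sign is fixed so its largest-magnitude loading is positive,
making the embedding deterministic. This is PCA of the distance rows,
*not* classical metric MDS on squared distances; the two differ and the
row-PCA reading is implemented deliberately. Degenerate matrices (all
rows equal) embed at the origin with zero explained fractions. Default
dimensionality: k=2 for maps, k=3 for analyses.

A reference map embeds the deduplicated union of several lipidomes
(identity = rendered SMILES) and records a membership mask per lipidome.

On the built-in phosphatidylinositol series (sn1 16:0; sn2 10:0–19:0 and
14:1(9)–19:1(9)) the first two components carry ≈97 % of the variance
and in-plane distances grow monotonically with sn2 length. This series
is a package-defined surrogate with the same design variables (sn2
length scan, single unsaturation) as the classic 16-PI demonstration,
whose exact membership is not publicly specified; the published "95 %
in two components" is therefore checked as a ≥90 % property, not an
equality.

## The LUX score

Directed distance: `d_AB = mean_{a∈A} min_{b∈B} d(a,b)`, with zeros for
structures present in both sets included in the mean; the score is
`max(d_AB, d_BA)` — an average-directed (modified) Hausdorff distance,
not the classical max–min Hausdorff. Ties in "most similar lipid" need
no tie-break (only the distance enters). Structure identity is exact
SMILES equality even in coordinate spaces, so a shared species always
contributes zero regardless of embedding noise.

`space="full"` uses Levenshtein on the strings; `"2d"`/`"3d"`/`"kd"` use
Euclidean distances between reference-map coordinates (one shared union
map for a set of lipidomes). At full rank the PCA coordinates are an
isometry of the centered descriptor rows, so `"kd"` scores equal scores
computed directly on the matrix rows (tested); truncated spaces
approximate them. `StructureSpace` precomputes all structure-level
distances once so clustering and the error model scale to repeated
evaluations. Abundance-weighted scoring is deliberately out of scope —
the score measures repertoires, not concentrations.

## Lipidome comparison and the error model

Alternative pairwise measures: percentage of common lipids
(100·|A∩B|/|A∪B|) and an abundance distance (1 − Pearson r over the
union profile, absent species at 0 mol%).

Complete-linkage clustering is implemented directly (max inter-cluster
distance, merge ties broken by lexicographically smallest label sets so
results are reproducible) and cross-checked against scipy's cophenetic
distances on random inputs. The default `input_mode="rows"` takes
Euclidean distances between the rows of the supplied score matrix first
— the `dist()` + `hclust()` idiom used with such matrices — while
`"direct"` treats the input as the dissimilarity itself.

Error model: per species, in stable id order, `x' = x + N(0, s)`; the
species is kept at abundance `x'` iff `x' > t_detect`. No mol%
renormalization is applied after perturbation (the procedure modifies
presence and quantity only). Removal is structural: a dropped species
changes the LUX structure sets. Three parameter presets are bundled
(`t_detect`, `s` in mol%): (0.003, 0.001), (0.003, 0.002),
(0.006, 0.004) — chosen so that only low-abundance species are
significantly affected at yeast-lipidome abundance scales. Branch
support counts, for each internal clade of the unperturbed reference
tree, how many of the (default 100) perturbed replicates reproduce it;
with s=0 every count equals the iteration count, which is tested.

## Synthetic lipidomes

`synthetic_lipidome_pair` draws random valid species (chains of 12–24
carbons, optional single double bond, optional hydroxyl on amide chains)
across a PC/PE/PI/TAG/CER class mix, deduplicated by rendered SMILES,
and assembles two lipidomes of `count` species sharing exactly
`round(overlap·count)` structures, with abundances uniform on (0, 10]
mol% — the scale of mol% survey data. Everything is reproducible from a
single seed. These generators exercise set overlap, abundance noise and
class structure, but not features of real lipidomes such as correlated
chain-length distributions, isomer ambiguity, or heavy-tailed abundance
profiles — so passing tests demonstrate the machinery's correctness, not
biological performance. Error-model reproducibility is exercised on 8
synthetic lipidomes of 50 species (pairs at 50 % overlap), a size chosen
to match survey-scale datasets while keeping the suite quick.

## Numerical choices and limitations

* Distances live in [0,1]; coordinate-space LUX matrices are rescaled by
  their maximum when it exceeds 1 so dendrogram input obeys the same
  contract (clustering is scale-invariant).
* Representative-isomer selection (smallest mean Levenshtein distance to
  the other isomers) detects ties within 1e-9 and returns the lowest
  index; on the ceramide scan the central 4..16 positions tie and
  position 4 is returned (verified against an exact rational oracle).
* Float output is written at 6 significant digits; tests compare with
  tolerances, never strings.
* The SMILES parser covers the template subset only (C/N/O/P/S, branches,
  `=`/`#`, single-digit ring closures) — no aromaticity, stereochemistry
  or general canonicalization; sterol and glycan templates stay within
  digits 0–9 by construction.
* Abundances are mol% throughout; no auto-normalization is performed.
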