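# Methods

## The quantity being computed

A heme cofactor's Fe-porphyrin core (25 heavy atoms: Fe, 4 pyrrole
nitrogens, 20 ring carbons) is planar with D4h symmetry at equilibrium, but
protein environments deform it, and the deformation pattern — saddled,
ruffled, domed — correlates with chemical function.  Normal-coordinate
structural decomposition (NSD) quantifies this by writing the deviation of
an observed core from the planar reference as amplitudes along the
low-frequency normal modes of the reference:

    d_k = Q_k . D_heme

where D_heme is the 75-component displacement (observed minus reference,
after rigid superposition) and Q_k are twelve unit-norm mode vectors:
saddling (B2u), ruffling (B1u), doming (A2u), waving(x)/(y) (Eg) and
propellering (A1u) out of plane; meso-stretching (B2g), N-pyrrole
stretching (B1g), translation(x)/(y) (Eu), breathing (A1g) and rotation
(A2g) in plane.

## Reference geometry

The exact quantum-chemical equilibrium geometry of Fe-porphine is not
needed for mode *shapes*, so the package builds an idealized core in closed
form from canonical bond lengths (Fe-N 2.00 A, N-Ca 1.38 A, Ca-Cb 1.44 A,
Cb-Cb 1.35 A, Ca-Cmeso 1.39 A) plus one free angle, the pyrrole Ca-N-Ca
interior angle.  Its default of 108 deg was chosen so that the
cross-pyrrole Ca..Ca separation (2.23 A) clears the 2.2 A bonded-distance
rule with a clear margin: at the more typical 105.5 deg that separation is
2.196 A, within 4 mA of the cutoff, and the canonical count of 32 bonded
pairs would be numerically fragile.  All parameters are overridable;
construction fails loudly if the macrocycle cannot close within 1e-3 A.
Frame convention: Fe at the origin, N atoms on the x/y axes, z normal to
the plane; atom order is fixed (FE; NA..ND; ring carbons A,B,C,D; meso
carbons) so 75-vectors are comparable everywhere.

## Force field and mode basis

The modes are eigenvectors of the mass-weighted Hessian
M^(-1/2) (grad^2 E) M^(-1/2).  E is a harmonic valence force field with
every internal coordinate's rest value taken from the reference itself:
bond stretches over the 32 bonded pairs (k_r = 1.0), angle bends at all 54
bond pairs sharing an atom (k_theta = 0.3), and harmonic torsions around
every bonded path whose inner triples are not collinear (k_phi = 0.1;
84 terms — torsions through the linear N-Fe-N paths are excluded as
singular).  Force constants are in arbitrary consistent units: only mode
shapes enter the projection, never frequencies, and shapes within each
one-dimensional irrep are pinned by symmetry.  A ±20% change in any
constant moves each named mode's direction by less than cos 0.95 (tested).

The Hessian is built by symmetric four-point central differences
(step 1e-4 A), which is exact through O(h^2) and symmetric in (i, j) by
construction.  On the reference, the spectrum has exactly 6 near-zero
eigenvalues (rigid motions; threshold 1e-6 x largest eigenvalue) and 69
internal modes, i.e. 3N-6 for N = 25.

Eigenvectors are assigned to D4h irreducible representations with exact
group-theoretic projectors built from the 16 point-group operations
(each a 3x3 orthogonal matrix plus the label permutation it induces).  The
lowest-eigenvalue internal mode of each relevant irrep is selected.  The
two degenerate pairs (Eg, Eu) arrive in an arbitrary internal orientation;
the gauge is fixed by maximal overlap with x/y-aligned analytic seed
templates followed by Gram-Schmidt.  Naming convention for the two in-plane
g species the literature leaves unlabelled: radial nitrogen motion
(x^2-y^2 pattern with N on the axes) is B1g = N-pyrrole stretching; radial
meso-carbon motion (xy pattern on the diagonals) is B2g = meso-stretching.

Two deliberate choices:

* **Rigid-body projection.**  Mass-weighted eigenvectors are orthogonal to
  rigid motions in the mass-weighted metric, but dividing by sqrt(m)
  re-introduces rigid components in plain Cartesian space (the doming
  vector, for instance, acquires ~10% uniform z-translation, because Fe is
  much heavier than C/N).  Least-squares superposition removes exactly the
  rigid part of any displacement, so leaving it in the basis would make an
  injected 0.5 A doming amplitude read back as ~0.45.  The package
  therefore projects the 6-dimensional rigid space out of each Cartesian
  mode vector before normalization.  Amplitudes are then rigid-motion
  invariant and injected amplitudes recover exactly.
* **No re-orthogonalization.**  The projection is the plain inner product
  with each unit mode vector — no pseudo-inverse.  Because all modes here
  belong to distinct irreps (the Eg/Eu partners are orthogonalized within
  their pair), the Gram matrix is diagonal to ~1e-12 and cross-talk is
  negligible; the basis validity check still only requires self-inner
  products >= 0.99 and pairwise inner products <= 0.10, the regime a
  loaded external basis (e.g. one derived from a DFT calculation with
  hydrogens, restricted to heavy atoms) is expected to occupy.

Sign conventions are fixed by positive overlap with the analytic templates
(e.g. positive doming displaces Fe toward +z relative to the ring); they
are arbitrary but deterministic and persist through the basis file format,
a 12-block xyz-like text with a 1e-9 round-trip guarantee.  A user-supplied
basis file replaces the computed one after re-validation.

## Extraction and annotation rules

* Heme residues are matched by compound ID on exactly {HEM, HEA, HEB, HEC,
  HEO}; comp IDs are stored verbatim.
* Per atom identity, only PDB model 1 is used; among altlocs '.' is kept
  when present, else 'A'; an atom present only with other altlocs counts
  as missing.
* A heme missing any of the 25 skeleton atoms is skipped (logged with
  identity and reason), never partially analyzed.
* Resolution is read from `_refine.ls_d_res_high`, falling back to
  `_reflns.d_resolution_high`, else null.  Absent header fields are null,
  never guessed.
* Keyword-to-function grouping is a shipped editable TSV
  (`hemensd/data/keyword_functions.tsv`); unknown keywords pass through
  unmapped.
* Axial ligands: any residue/molecule (grouped by chain + residue index)
  with an atom within 3.1 A of FE; per candidate the distance is the
  minimum over its atoms; at most the two nearest are kept (coordination
  number 0-2), ties broken by distance, then chain, then residue index.
  Waters and ions are candidates by default ("other small molecules");
  an exclusion list is available.  The heme's own atoms never count.
* Organism = first two words; EC = first three class labels.

## Descriptors

* d_OOP: the N4 plane is the span of the two largest eigenvectors of the
  nitrogen coordinate covariance; d_OOP is the projection of FE (relative
  to the N centroid) on the smallest eigenvector.  The normal's sign is
  arbitrary, so it is oriented toward axial ligand #1 when one exists;
  otherwise the magnitude is reported with the sign flagged unresolved.
* Propionate torsions C1A-C2A-CAA-CBA and C4D-C3D-CAD-CBD, standard signed
  convention in (-180, 180].  Orientation: up if < 0, down if > 0; the
  measure-zero boundary 0 (and 180) is assigned down for determinism.
* Coverage: c = (S_heme - S_complex)/S_heme summed over the 25 skeleton
  atoms, Shrake-Rupley SASA via mdtraj with probe radius 1.4 A, 960 sphere
  points, mdtraj's Bondi-type radii; only C/N/O/S/Fe atoms participate.
  Note Shrake-Rupley is local — it does not detect enclosed cavities — so
  a synthetic occluding shell must sit close to the heme (the fixture
  default is a Fibonacci sphere at 6 A) to realize full burial.
* Binding-pocket volume is not computed; pocket-volume output from an
  external tool can be joined onto the entry table by identity columns.

## Feature analysis

* Histograms: per-mode, per-group counts on shared bin edges; a resolution
  filter within [1.4, 8.2] A; empty selections return a status, not an
  error; counts are conserved across groups.
* PCA operates on Cartesian coordinates after iterative fit-to-mean: the
  mean starts at the first structure, all structures are rigidly fitted to
  it over the chosen fit atoms, and the mean is recomputed until it moves
  < 1e-6 A RMSD (max 50 iterations).  Eigenvectors are exportable as
  25-atom displacements and are compared against the saddling/ruffling/
  doming modes by inner product.
* LDA on the 12 amplitudes: shared-covariance class-conditional model;
  direction = S_pooled^-1 (mu2 - mu1), normalized, with a ridge of
  1e-6 x trace(S)/12 added only when S is rank-deficient (flagged in the
  result).  The direction is also expressed as the corresponding linear
  combination of mode vectors (a 75-component displacement).  The
  implementation agrees with scikit-learn's LDA direction to cos >= 0.999
  on well-conditioned data (tested).
* Clustering: K-means, spectral, agglomerative, Gaussian mixture
  (scikit-learn), always with k = number of target groups, seed pinned
  (default 0); the tested artifact is the cluster-by-group contingency
  table.

## Synthetic data

The fixture generator produces exactly the inputs the analysis consumes:
distorted cores (reference + sum of amplitude x mode + isotropic Gaussian
coordinate noise + optional rigid transform, all under explicit seeds),
propionate stubs realizing requested torsions to 1e-9 deg, ligand atoms
placed exactly on the N4 normal, occluding Fibonacci shells, and minimal
mmCIF files exercising the model/altloc/intactness rules.  Default study
conditions used in tests: amplitudes up to 0.5 A (the regime where the
linear decomposition is meaningful; superposition perturbs pure modes only
at second order), coordinate noise sigma = 0.02 A (a fraction of a typical
high-resolution coordinate uncertainty), LDA/cluster groups at saddling
+/-0.5 A with sigma = 0.05 A, and 100-200 replicates where sampling error
matters.

What the fixtures do **not** emulate: real protein environments (packing,
covalent heme c linkages, partial occupancies beyond simple altloc pairs),
correlated experimental noise, or a DFT-grade force field.  Passing tests
therefore demonstrate the correctness of the decomposition machinery and
rules, not agreement with any particular quantum-chemical mode basis; for
numeric parity with an external basis, load it through the basis file
interface.

Noise propagates to amplitudes simply: projecting i.i.d. coordinate noise
of sd sigma onto a unit mode vector gives amplitude noise of sd ~ sigma.
Recovery tests therefore use tolerances of a few sigma per replicate and
3-standard-error bounds on means, rather than fixed absolute bounds.

## Numerical choices

* Finite-difference step 1e-4 A (validated range (1e-5, 1e-2)).
* Zero-eigenvalue threshold: 1e-6 x largest eigenvalue.
* Irrep match requires projector overlap >= 0.5, else a mode-identification
  error reporting the best assignments.
* Kabsch fits are unweighted over all 25 skeleton atoms, proper rotations
  only; degenerate (rank < 2) point sets are rejected.
* Basis file round trip at 1e-9; atom-order permutations restored from the
  header.

## Known limitations

* Mode eigenvalues are in arbitrary force-field units and should not be
  interpreted as frequencies.
* The NSD superposition target is the idealized reference, not a dataset
  mean (the PCA tool, by contrast, fits to the iterated mean).
* HEB's compound-ID ambiguity in the source data (it may denote heme b or
  c) is preserved verbatim.
* Dataset-level population statistics (ligand/function/fold compositions)
  depend on whichever structure snapshot is supplied and carry no claims
  here.
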