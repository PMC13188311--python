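# Methods

## Model

A molecule's torsional conformation is discretized into a string of N
bits, one per rotatable bond. A bond is *rotatable* here iff it is a
non-ring single bond between two heavy atoms, each of which has at least
one heavy neighbor besides the other (terminal and ring bonds carry no
torsional state; double bonds are configurational, not conformational,
and are excluded). Bit *i* takes values 1..m<sub>i</sub>, the
multiplicity of the torsion pattern matched to the bond.

Topological symmetries — automorphisms of the labeled molecular graph —
act on the strings by permuting bits. Bit strings in one orbit describe
the same physical torsional state under different atom numberings; the
orbit's lexicographically smallest member is the canonical TABS. The
number of orbits (nTABS) is computed exactly by Burnside's lemma: sum
|Fix(g)| over the bit-permutation group and divide by |G|. |Fix(g)| is
the product over cycles of g of the cycle's common multiplicity, because
a string is fixed iff it is constant on every cycle. All arithmetic is
exact Python integers — nTABS routinely exceeds 10^20 for flexible
molecules — and the final division asserts a zero remainder, which is a
cheap structural self-check: a non-closed "group" almost always breaks
exact divisibility.

## Conventions

* **Action.** g·s places the value of bit i at position g(i) (left
  action). Counting is convention-independent; canonical forms are not,
  so this is fixed.
* **Bit values** are 1-based everywhere at the API surface; strings
  serialize as hyphen-separated integers (`"1-3-2"`, empty string `"-"`).
* **Angles** are signed dihedrals in degrees, IUPAC convention,
  normalized to (−180, 180]. Bins are half-open (lower, upper] and wrap
  across ±180°: with edges b₁ < … < b_k, bin 1 is (b_k − 360, b₁] and
  bin i is (b_{i−1}, b_i]. Boundary angles therefore land
  deterministically; there is no smoothing or peak snapping.
* **Bit order.** Bits are sorted by the pair of canonical atom ranks of
  their bond atoms (ties by atom indices), making TABS strings stable
  under input reordering. Reference quadruples pick, on each side, the
  heavy neighbor with the smallest canonical rank.
* **Degenerate geometry.** A collinear atom triple makes a dihedral
  undefined and raises an error; silently binning it would corrupt
  counts.

## Symmetry handling

Automorphisms are enumerated on the heavy-atom graph by backtracking
(VF2, via NetworkX) with atoms constrained to their (element, formal
charge, aromaticity) class and bonds to their (order, aromaticity)
class. Hydrogens only permute within a heavy atom's coordination sphere
and can never move a torsion bond, so they are irrelevant to the bit
action. The atom group is projected to bit permutations (bond {b,c} ↦
{σ(b), σ(c)}), **deduplicated**, and re-verified for closure: Burnside
applies to the group actually acting on the strings, and |G| is the
order of that image group. A projected permutation that maps a torsion
bond to a non-torsion bond, or across multiplicities, is a hard error —
it would mean the pattern matching is not symmetry-consistent.
Stereochemistry is deliberately ignored (the symmetry is purely
topological), so enantiomeric torsional states merge; the automorphism
search is capped (default 10^5) and errors out rather than truncating.

## Torsion library

The shipped library is a small curated YAML set — aromatic–aromatic (4
bins), amide (2), conjugated sp²–sp² (2), sp³–sp² (3), sp³–sp³ (3) and a
generic 3-bin catch-all — with bin edges at the barriers between the
well-known rotamer wells of each class (e.g. −120°/0°/120° separating
the anti and two gauche wells of an sp³–sp³ bond). The counting
machinery is library-agnostic and is validated against abstract systems,
not against these particular bins; the published CSD-derived library can
be supplied as a drop-in YAML file. How bins should be derived from
torsion-profile peaks is out of scope — bins are library inputs. Locally
degenerate rotors (e.g. a terminal phenyl whose 180° flip is identity)
are the library author's responsibility, folded into multiplicities.
Pattern specificity is by file order; the catch-all must stay last.

## Categorization framework

TABS equality of a conformer pair is the condition (ground-truth axis);
the thresholded continuous metric is the predictor. A similarity metric
calls a pair "same" at value ≥ threshold, a distance metric at value ≤
threshold. PPV and NPV with a zero denominator are reported as missing,
never as 0 or 1. The optimal threshold maximizes min(PPV, NPV) by
default — the symmetric scalar reading of "maximal values of both";
product and fixed-NPV criteria are options, since the literature does
not pin the criterion down. Ties break toward the stricter "same" call.
The built-in RMSD adapter minimizes over automorphism-induced atom
mappings (RDKit `GetBestRMS`): a symmetry-naive RMSD would disagree with
TABS on symmetry-related conformers by construction. The shape Tanimoto
adapter wraps the PubChem shape-alignment code in RDKit with atom
features enabled; it is an adapter, not a reimplementation.

## Synthetic data

`random_system` draws abstract bit systems (N ∈ [1,6], m ∈ [1,4] by
default) with groups generated by random multiplicity-respecting
permutations, closed by construction — the population on which the
Burnside path is proven equivalent to brute-force enumeration.
`synthetic_ensemble` emulates only the *label-level* structure of a
conformer ensemble: TABS sampled uniformly from S, pair scores drawn
from Normal(0.95, σ) for equal-TABS pairs and Normal(0.60, σ) for
unequal ones (σ = 0.05 by default, clipped to [0,1]). The defaults give
clearly separated but overlapping classes, roughly matching the ~0.8–1.0
predictive values seen for real shape scores; σ = 0 is the
perfect-separation limit. These ensembles contain no geometry: a green
sweep test establishes the bookkeeping of the framework, not that any
real metric agrees with TABS. Real-geometry checks use small RDKit-embedded
ensembles of butane and 1,2-diphenylethane.

## Numerical and scaling choices

* Exhaustive enumeration is an oracle only, capped at 10^7 strings by
  default; the naive counter prunes by early-exit minimality testing.
* Group closure from generators is bounded (default 10^6 elements).
* The Burnside path is O(|G|·N); the test suite asserts the invocation
  count of the fixpoint counter equals |G| on systems with M ≈ 10^12.
* Flexibility boundaries are nTABS < 500 (low), 500 ≤ nTABS < 10,000
  (medium), ≥ 10,000 (high); the medium class is read as the interval
  between the two published cut-offs.

## Limitations

* The shipped torsion library is a minimal, plausible default, not the
  published CSD-derived set; absolute nTABS values depend on the
  library.
* Symmetries act only by permuting bits. A symmetry that would also
  relabel bin values within a bit (e.g. a dihedral read from the other
  end mapping an angle to its negative and permuting mirror bins) is not
  modeled; such effects must be folded into the library's bins.
* No conformer generation, minimization or 3D point-group detection;
  ensembles are inputs.
* Molecules whose heavy-atom automorphism group exceeds the cap are
  rejected.
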