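# tabscount

Torsion angular bin strings (TABS) for conformer ensembles: exact counting
of a molecule's discrete torsional states and threshold-free grouping of
conformers, for cheminformatics and drug-discovery workflows that need to
size or deduplicate conformational ensembles.

## The idea

Each rotatable bond of a molecule is matched against a library of torsion
patterns, each carrying angular bins derived from the known rotamer wells
of that bond class. A conformer's dihedrals are then discretized into a
string of N integer *bits*, bit *i* taking values 1..m<sub>i</sub> (the
pattern's *multiplicity*). The set *S* of all such raw strings has

&nbsp;&nbsp;&nbsp;&nbsp;M = |S| = ∏<sub>i</sub> m<sub>i</sub>.

A molecule's topological symmetries — atom permutations preserving element
types and connectivity — permute the bits, so different raw strings can
describe the same torsional state under a different atom numbering. A
**TABS** is the lexicographically smallest member of such an equivalence
class (orbit), and the number of distinct torsional states is the number
of orbits. By Burnside's lemma,

&nbsp;&nbsp;&nbsp;&nbsp;nTABS = (1/|G|) ∑<sub>g∈G</sub> |Fix(g)|,

where G is the bit-permutation group and |Fix(g)| — the number of strings
fixed by g — is just the product of the common multiplicity over each
cycle of g. The whole count costs O(|G|·N) and never enumerates the
exponentially large S; a brute-force enumerate-and-deduplicate oracle is
kept for cross-validation on small systems. nTABS is an upper-bound
estimate of the conformer-ensemble size and a flexibility measure (low:
nTABS < 500, medium: 500 ≤ nTABS < 10,000, high: ≥ 10,000).

The package also ships the confusion-matrix framework for comparing the
threshold-free TABS grouping of conformer pairs with thresholded
continuous metrics (symmetry-aware heavy-atom RMSD, shape Tanimoto):
PPV = TP/(TP+FP) and NPV = TN/(TN+FN) as a function of the metric
threshold, with optimal-threshold selection.

## Worked example

```python
from tabscount import analyze_molecule, ntabs_naive

result = analyze_molecule("c1ccccc1CCc1ccccc1")   # 1,2-diphenylethane
print(result.n_bits, result.multiplicities)        # 3 (3, 3, 3)
print(result.group.order)                          # 2
print(result.naive_state_count)                    # 27
print(result.ntabs)                                # 18
print(ntabs_naive(result.system))                  # 18
```

The molecule has three rotatable bonds (phenyl–CH₂, CH₂–CH₂, CH₂–phenyl),
each matched to a 3-bin pattern, so there are 27 raw strings. The
end-to-end flip exchanges the two phenyl bits, and Burnside gives
(27 + 9)/2 = 18 distinct torsional states — identical to the brute-force
enumeration. Or from the shell:

```
$ tabscount ntabs demo.smi --check-naive
molecule,n_bits,multiplicities,group_order,naive_states,ntabs,flexibility,ntabs_naive,agree
butane,1,3,1,3,3,low,3,True
biphenyl,1,4,1,4,4,low,4,True
diphenylethane,3,3x3x3,2,27,18,low,18,True
ethyl_benzoate,3,3x3x2,1,18,18,low,18,True
```

`tabscount tabs ENSEMBLE.sdf` labels every conformer of a multi-record
SDF with its raw and canonical TABS; `tabscount compare` sweeps a metric
threshold against the TABS grouping and reports PPV/NPV and the optimal
threshold; `tabscount selftest` runs the Burnside-vs-enumeration battery
on seeded random systems.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the package's headline computations from scratch: the
two-equivalent-torsion worked example (9 raw strings, 6 TABS), a
500-system Burnside-vs-enumeration oracle battery, exact nTABS for the
bundled molecule fixtures, and a synthetic-ensemble PPV/NPV threshold
sweep.

## Layout

- `src/tabscount/bitstrings.py` — multi-radix strings, orbits, canonical forms
- `src/tabscount/burnside.py` — permutations, groups, fixpoint counting, nTABS
- `src/tabscount/torsionlib.py` — torsion-pattern library and bond matching
- `src/tabscount/symmetry.py` — graph automorphisms → bit-permutation group
- `src/tabscount/tabs_assign.py` — conformer dihedrals → canonical TABS
- `src/tabscount/categorize.py` — PPV/NPV framework and metric adapters
- `src/tabscount/fixtures.py` — seeded synthetic systems and ensembles
- `docs/methods.md` — model assumptions, conventions and design notes
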