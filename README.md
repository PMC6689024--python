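# cbekit

Quantification and characterization of CRISPR **cytosine base editors**
(CBEs) from targeted amplicon deep sequencing.

CBEs are deaminase–nCas9 fusions that convert C·G base pairs to T·A inside
a window of the 20-nt protospacer (positions numbered 1–20, PAM at 21–23).
Different deaminases edit different regions of that window and favour
different sequence contexts; comparing editors therefore requires a common
quantitative pipeline.  `cbekit` implements that pipeline end to end, for
people benchmarking new editors or choosing one for a target:

1. **Quantify** — demultiplex reads by exact barcode prefix, trim 3′ tails
   with Phred quality < 15, place each read on the amplicon by an exact
   20-mer seed on either strand, and tabulate observed bases at every
   position of a fixed 43-bp window (30 nt upstream of the PAM through
   10 nt downstream).  The per-position conversion frequency is
   `count(converted base) / depth`.
2. **Editing windows** — per sgRNA, normalize the C→T profile so its
   best-edited cytosine equals 1; the per-sgRNA *editing scope* is the set
   of C positions with ≥ 40 % raw frequency; the editor's *comprehensive
   editing window* (CEW) is the set of positions whose mean normalized
   efficiency across the sgRNA panel exceeds 0.6.  Editors are labeled
   FSCBE / BSCBE / BRCBE (forward-shifted / backward-shifted / broad-range)
   by where the CEW sits.
3. **Substrate preference** — pool C sites across the panel, keep position
   classes with at least one site at ≥ 0.8 normalized frequency, group by
   the dinucleotide 5′ (NC) or 3′ (CN) of the edited C, test by one-way
   ANOVA (p < 0.05), and report orderings such as `TC/AC>CC>GC`.
4. **Specificity** — with onCʰ and offCʰ the highest C→T frequencies in the
   on- and off-target windows, specificity = (onCʰ − offCʰ)/onCʰ; `N.Sp.`
   marks off-target activity exceeding on-target, and `no-activity` marks
   silent on-targets.

Because public read archives are not needed to validate the algebra, the
package ships a **read simulator** with a closed-form truth oracle:
position-dependent, context-modulated C→T conversion plus uniform
substitution error and Phred qualities, so every downstream stage can be
checked against known ground truth.

## Worked example

```python
from cbekit import (EditorProfile, simulate_reads, quantify_reads,
                    expected_t_frequency)
from cbekit.simulate import make_synthetic_site
from cbekit.windows import analyze_editor

site = make_synthetic_site("demo", seed=1, c_positions={4: "A", 6: "T", 8: "G"})
editor = EditorProfile("demo_be", p_edit={4: 0.6, 6: 0.6, 8: 0.6})

batch, truth = simulate_reads(site, editor, n_reads=20_000, seed=42)
table = quantify_reads(batch, site).tables["default"]

print(expected_t_frequency(editor, site, 4))   # 0.5995333333333333
print(table.c_to_t_frequencies()[4])           # 0.5962137061795173

res = analyze_editor("demo_be", {"demo": table.c_to_t_frequencies()})
print(sorted(res.cew), res.class_label)        # [4, 6, 8] FSCBE
```

The closed form `q(1−e) + (1−q)e/3` (edit probability q = 0.6, sequencing
error e = 0.001) predicts 0.5995; the simulated 20,000-read sample recovers
0.5962, within one binomial standard deviation.  The three designed
cytosines form the CEW and the editor, active only at positions 4–8, is
classified forward-shifted.

The same stages are available on the command line (`cbekit simulate`,
`quantify`, `windows`, `preference`, `specificity`), and `cbekit run --out
OUTDIR` executes the whole chain on the bundled archetype editors, writing
conversion tables, window/scope tables, preference ANOVA results,
specificity scores and a manifest that records every threshold and seed.
Re-running an identical configuration reproduces byte-identical outputs.

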