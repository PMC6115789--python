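"""Local-structure accessibility of a target site.

Folds the window around a candidate site and reports the minimum folding
energy plus the fraction of site positions left unpaired in the MFE
structure.  A strongly negative fold MFE with a mostly-paired site means
the site is likely occluded by target secondary structure; the pipeline
reports these numbers as supplementary evidence, it never filters on them.
"""

from mirtarp import NucSequence, fold_local, site_accessibility_report

# a target whose 5' half folds into a stable GC hairpin and whose 3' half
# is unstructured poly-purine sequence
hairpin = "G" * 10 + "AAAA" + "C" * 10
target = NucSequence("toy-target", hairpin + "AGAAGAAAGAAAGAAAGGAAAGAA")

for name, site in (("inside the hairpin stem", (14, 24)),
                   ("in the unstructured tail", (30, 40))):
    fold = fold_local(target, site, flank=20)
    frac, mfe = site_accessibility_report(fold, site)
    print(f"site {site} {name}:")
    print(f"  window {fold.window_start}-{fold.window_end}, "
          f"fold MFE {mfe:.2f} kcal/mol, unpaired fraction of site {frac:.2f}")
print("(the stem site is paired in a stable fold; the tail site is fully accessible)")
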