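"""The full conduction-velocity grid: 3 fiber types x 3 genotypes x +/- E3G.

Full-size fibers (100 cells) with 10 stabilization beats; the ventricular
family integrates at dt = 1 us, so expect roughly 10-15 minutes on one CPU.
Writes a tidy CSV next to this script.  The same grid is available from the
command line as ``cardiokit table4 --out cv_table.csv``.
"""
import pathlib

from cardiokit import table4

out = pathlib.Path(__file__).with_name("cv_table.csv")


def progress(row):
    cv = "block" if row["conduction_block"] else f"{row['cv_cm_per_s']:.2f}"
    print(f"{row['model']:24s} {row['genotype']:10s} {row['e3g']:8s} {cv}")


table = table4(schedule="paper", out_csv=str(out), progress=progress)
print(f"\nwrote {out}")
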