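"""Differential-expression filtering with planted ground truth.

Simulates a DE table for the 6289-gene genome (one chromosome, three
plasmids), filters at |signed fold-change| >= 2.5 with BH-adjusted
p <= 0.05, and summarizes by replicon.

Run: python examples/04_deg_filter.py
"""

from lcoscreen.deg import DEGRecord, ddct_fold_change, filter_deg, replicon_summary
from lcoscreen.synth import simulate_deg_table

df, truth = simulate_deg_table(seed=1)
records = [DEGRecord(g, r, f, p) for g, r, f, p in
           zip(df.gene_id, df.replicon, df.fold_change, df.padj)]
kept = filter_deg(records, fc_threshold=2.5, alpha=0.05)

print(f"genes          {len(records)}")
print(f"DEG            {len(kept)} ({sum(r.up for r in kept)} up-regulated)")
print("\nper-replicon breakdown:")
print(replicon_summary(kept))

# qPCR-style validation of a single gene: 2^-ddCt fold-change.
fc = ddct_fold_change(ct_target_cond=20.1, ct_ref_cond=15.0,
                      ct_target_ctrl=22.4, ct_ref_ctrl=15.1)
print(f"\nexample ddCt fold-change: {fc:.2f}x "
      "(target vs 16S reference, condition vs control)")
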