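"""The full measurement-uncertainty budget from the bundled study tables.

Pools the per-level precision estimates by RMS, runs the trueness
assessment against the ERM-AD623 certificate, and combines everything
into the expanded uncertainty of a 4-replicate single-run result.
"""
from dropval import bias_assessment, combined_uncertainty, pool_rms, reference

rows = reference.ACCURACY_STUDY
s_rep = pool_rms([r["s_repeat_rel"] for r in rows.values()])
s_run = pool_rms([r["s_run_rel"] for r in rows.values()])
u_prec = pool_rms([r["u_precision_rel"] for r in rows.values()])
print(f"pooled repeatability      s_repeat = {100*s_rep:4.1f} %")
print(f"pooled run-to-run         s_run    = {100*s_run:4.1f} %")
print(f"pooled precision          u_prec   = {100*u_prec:4.1f} %")

measured = {k: v["c_meas"] for k, v in rows.items()}
cert = [c for c in reference.ERM_AD623 if c.level_id in measured]
be = bias_assessment(measured, cert, u_prec)
print(f"\nper-level bias (%): " +
      ", ".join(f"{k} {100*v:+.1f}" for k, v in be.bias_rel.items()))
print(f"mean bias = {100*be.mean_bias_rel:+.1f} %, "
      f"u_bias = {100*be.u_bias_rel:.1f} %, U_bias = {100*be.U_bias_rel:.1f} %")
print("bias significant?", be.significant,
      "(|mean bias| must exceed U_bias to count as significant)")

U = combined_uncertainty(s_rep, s_run, reference.DROPLET_VOLUME_REL_U,
                         be.u_bias_rel, n_meas=4, n_run=1)
print(f"\nexpanded uncertainty (k=2) of a 4-replicate single-run mean:"
      f" U_meas = {100*U:.1f} %")
print("this is the +- interval, relative to the result, that covers the")
print("true concentration with ~95 % confidence for this method.")
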