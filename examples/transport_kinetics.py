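"""Compare PTS and ABC uptake kinetics at matched translocation capacity.

Builds the baseline rate set (glucose-PTS / maltose-MalE values), evaluates
both transport systems over a concentration range, and shows how the ABC
half-saturation concentration is set by binding-protein abundance rather
than by the binding protein's intrinsic K_D.
"""

import numpy as np

from uptakealloc import (
    AbcPools,
    TransportParameters,
    abc_mm_approx,
    abc_steady_state,
    effective_half_saturation,
    pts_uptake,
    specific_affinity,
)

params = TransportParameters.baseline()
print(f"K_T  = {params.K_T*1e3:.1f} uM   (PTS half-saturation, intrinsic)")
print(f"K_D  = {params.K_D*1e3:.1f} uM   (binding-protein dissociation constant)")

T_total = 0.001  # 1 uM transport units, periplasmic basis
for bp_total in (0.001, 0.01, 0.1, 1.0):
    pools = AbcPools(BP_total=bp_total, T_total=T_total)
    fit = effective_half_saturation(
        lambda s: abc_steady_state(s, pools, params).v_c)
    _, mm = abc_mm_approx(0.0, pools, params)
    print(f"[BP] = {bp_total*1e3:6.1f} uM -> exact K_M = {fit.K_M*1e6:8.2f} nM, "
          f"closed-form K'_M = {mm.K_M*1e6:8.2f} nM, "
          f"specific affinity a' = {specific_affinity(fit):.3g} /s")

v_pts = pts_uptake(params.K_T, T_total, params)
print(f"\nPTS rate at S_p = K_T: {v_pts:.4f} mM/s  (= half of k2*[T] = "
      f"{0.5*params.k2*T_total:.4f})")
print("Raising [BP] lowers the ABC K_M ~1000-fold below K_D: affinity is an")
print("expression level, not a binding constant.")
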