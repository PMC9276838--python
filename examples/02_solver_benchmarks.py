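"""Closed-form solver checks: spreading resistance, perfusion, slab.

Each benchmark runs the production solvers on a scene with an analytic
solution and prints computed vs exact.  The sphere benchmark here uses a
2 mm electrode at coarse resolution for speed; the full 1 mm/0.5 mm study
lives in scripts/acceptance.py.
"""

from rfasim.benchmarks import (perfused_relaxation_benchmark,
                               slab_conduction_benchmark,
                               spreading_resistance_benchmark)

sph = spreading_resistance_benchmark((2.0,), a=2.0, b=40.0)
print("spreading resistance (a=2 mm sphere, sigma=0.333 S/m):")
print(f"  computed {sph.resistances_ohm[0]:.1f} ohm, "
      f"exact 1/(4 pi sigma a) = {sph.exact_ohm:.1f} ohm "
      f"({100 * abs(sph.relative_errors[0]):.2f}% off)")

relax = perfused_relaxation_benchmark()
print("perfused-block relaxation vs scalar ODE:")
print(f"  time constant {relax.tau_s:.0f} s, max error "
      f"{100 * relax.max_relative_error:.2f}% of the temperature rise")

slab = slab_conduction_benchmark()
print("two-material series slab steady state:")
print(f"  flux {slab.interface_flux_W_m2:.1f} vs exact "
      f"{slab.exact_flux_W_m2:.1f} W/m^2, profile error "
      f"{slab.max_profile_error:.1e} degC")
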