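"""Cross-validate the analytic-numerical route against the oracle.

Runs the bundled validation suite (coarse grids for speed): the Zakian
transform battery, the no-reaction agreement grid between the
Laplace/Zakian route and the method-of-lines finite-difference solver,
mass conservation, both reaction-mode comparisons, and a refinement check.
"""

from crfrelease import run_validation

report = run_validation(fast=True)
for chk in report["checks"]:
    flag = "ok  " if chk["passed"] else "FAIL"
    print(f"{flag} {chk['name']:<34} {chk['measure']:.3e} "
          f"(threshold {chk['threshold']:.0e})")
print(f"\noverall: {'PASSED' if report['passed'] else 'FAILED'}")
print("Measures are relative sup-norm gaps (oracle checks), relative "
      "drift (conservation), or worst inversion error (battery).")
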