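"""Physical constants used throughout the package (CODATA, via scipy)."""

from scipy.constants import Boltzmann as K_B  # J/K
from scipy.constants import Planck as H_PLANCK  # J*s
from scipy.constants import R as R_GAS  # J/(mol*K)

__all__ = ["K_B", "H_PLANCK", "R_GAS"]
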