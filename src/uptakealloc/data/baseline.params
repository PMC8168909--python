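# uptakealloc baseline cell parameters.
# Units: concentration mM, time s, length um, molecular mass kDa
# (mass density in kDa*mM is numerically g/L).
#
# Transport kinetics: measured values for E. coli's glucose PTS and the
# maltose/MalE binding-protein system; the ABC docking/undocking steps are
# ~100-fold slower than their PTS counterparts because they are limited by
# the slow diffusion of the bulky binding protein.
k1   = 20000.0              # /mM/s  PTS association; k2/K_T with K_T = 10 uM
k2   = 200.0                # /s     PTS translocation rate
k0f  = 100000.0             # /mM/s  substrate-binding protein association
k0r  = 100.0                # /s     substrate-binding protein dissociation (K_D = 1 uM)
k1p  = 198.01980198019803   # /mM/s  loaded-BP docking on transport unit; fixed by K_Tp = 10 uM
k2p  = 200.0                # /s     ABC translocation rate (= k2)
k3p  = 2.0                  # /s     BP undocking after translocation (= 0.01*k2p)

# Coarse-grained cell physiology. These are the package's defaults, chosen
# from generic bacterial physiology; rationale per value in docs/methods.md.
D    = 100.0                # um^2/s   free-substrate diffusivity (boundary layer/periplasm)
kE   = 0.5                  # /s       lumped catabolic-pathway turnover
K_ME = 0.1                  # mM
kW   = 1.0                  # /s       membrane-biosynthesis turnover
K_MW = 0.1                  # mM
kR   = 20.0                 # aa/s     ribosome elongation rate
K_MR = 0.1                  # mM
n_T  = 2000.0               # aa per transport unit
n_BP = 500.0                # aa per binding protein (= n_T/4)
n_E  = 1000.0               # aa per lumped metabolic-enzyme unit
n_M  = 1000.0               # aa per membrane-biosynthesis unit
n_R  = 7459.0               # aa of protein per ribosome
a_w  = 6e-07                # um^2 membrane area per membrane (lipid) unit
a_T  = 5e-05                # um^2 inner-membrane area per transport unit
f_SA = 0.5                  # fraction of inner membrane available to transporters
rho_cyto = 300.0            # g/L maximal cytoplasmic density
rho_peri = 100.0            # g/L maximal periplasmic density (no ribosomes/nucleoid)
m_S  = 0.18                 # kDa substrate (glucose-like)
m_A  = 0.1                  # kDa precursor (amino acid)
m_aa = 0.1                  # kDa per amino acid in protein
m_W  = 0.75                 # kDa per membrane unit
phi_O_cyto = 0.45           # fixed cytoplasmic "other"-protein fraction
phi_O_peri = 0.05           # fixed periplasmic "other"-protein fraction
r_min = 0.06                # um minimum radius (max surface-to-volume 50 /um)
S_ext = 1e-06               # mM external substrate (control variable; override per run)
include_W_in_cyto_density = false
strict_volume_basis = true
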