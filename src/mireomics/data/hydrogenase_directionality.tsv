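family	group	activity_class	provenance
[NiFe]	1a	h2_uptake	HydDB activity: H2-uptake (respiratory)
[NiFe]	1b	h2_uptake	HydDB activity: H2-uptake
[NiFe]	1c	h2_uptake	HydDB activity: H2-uptake
[NiFe]	1d	h2_uptake	HydDB activity: H2-uptake
[NiFe]	1e	h2_uptake	HydDB activity: H2-uptake
[NiFe]	1f	h2_uptake	HydDB activity: H2-uptake
[NiFe]	1g	h2_uptake	HydDB activity: H2-uptake
[NiFe]	1h	h2_uptake	HydDB activity: H2-uptake (high-affinity)
[NiFe]	1i	h2_uptake	HydDB activity: H2-uptake
[NiFe]	1j	h2_uptake	HydDB activity: H2-uptake
[NiFe]	1k	h2_uptake	HydDB activity: H2-uptake
[NiFe]	1l	h2_uptake	HydDB activity: H2-uptake
[NiFe]	2a	h2_uptake	HydDB activity: H2-uptake (aerotolerant)
[NiFe]	2b	h2_uptake	HydDB activity: sensory; grouped with uptake (binds H2, no net evolution)
[NiFe]	2c	h2_uptake	HydDB activity: sensory; grouped with uptake
[NiFe]	2d	h2_uptake	HydDB activity: H2-uptake
[NiFe]	3a	bidirectional	HydDB activity: bidirectional (F420-coupled)
[NiFe]	3b	bidirectional	HydDB activity: bidirectional (NADP-coupled)
[NiFe]	3c	bifurcating	HydDB activity: electron-bifurcation (MvhADG/HdrABC)
[NiFe]	3d	bidirectional	HydDB activity: bidirectional (NAD-coupled)
[NiFe]	4a	h2_evolving	HydDB activity: H2-evolving (energy-converting)
[NiFe]	4b	h2_evolving	HydDB activity: H2-evolving
[NiFe]	4c	h2_evolving	HydDB activity: H2-evolving
[NiFe]	4d	h2_evolving	HydDB activity: H2-evolving
[NiFe]	4e	h2_evolving	HydDB activity: H2-evolving (ferredoxin-driven)
[NiFe]	4f	h2_evolving	HydDB activity: H2-evolving
[NiFe]	4g	h2_evolving	HydDB activity: H2-evolving
[NiFe]	4h	h2_evolving	HydDB activity: H2-evolving
[NiFe]	4i	h2_evolving	HydDB activity: H2-evolving
[FeFe]	A	bifurcating	Group A unrefined; bifurcating is the dominant activity of sequenced members (see docs)
[FeFe]	A1	h2_evolving	HydDB activity: H2-evolving (fermentative)
[FeFe]	A2	h2_evolving	HydDB activity: H2-evolving
[FeFe]	A3	bifurcating	HydDB activity: electron-bifurcation (NAD/Fd-coupled)
[FeFe]	A4	bifurcating	HydDB activity: electron-bifurcation (formate/Fd-coupled)
[FeFe]	B	h2_evolving	HydDB activity: H2-evolving (ferredoxin-dependent)
[FeFe]	C1	h2_uptake	HydDB activity: sensory; grouped with uptake
[FeFe]	C2	h2_uptake	HydDB activity: sensory; grouped with uptake
[FeFe]	C3	h2_uptake	HydDB activity: sensory; grouped with uptake
[Fe]	Fe	bidirectional	Hmd methylene-H4MPT dehydrogenase; reversible H2 chemistry
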