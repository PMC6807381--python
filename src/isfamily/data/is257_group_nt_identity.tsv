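	IS257-2	IS257-1	IS257-3	IS431L	IS257R2	IS257R1	IS431mec	IS431R
IS257-2	100.00	88.86	88.83	86.15	86.29	86.31	86.82	86.57
IS257-1	88.86	100.00	92.52	94.92	94.80	95.06	95.57	95.32
IS257-3	88.83	92.52	100.00	95.30	96.70	95.18	95.69	95.44
IS431L	86.15	94.92	95.30	100.00	97.59	97.21	97.72	97.97
IS257R2	86.29	94.80	96.70	97.59	100.00	98.23	97.97	97.72
IS257R1	86.31	95.06	95.18	97.21	98.23	100.00	99.24	98.99
IS431mec	86.82	95.57	95.69	97.72	97.97	99.24	100.00	99.49
IS431R	86.57	95.32	95.44	97.97	97.72	98.99	99.49	100.00
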