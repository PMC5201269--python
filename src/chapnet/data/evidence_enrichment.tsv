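gene_id	myoconv_rnaseq	embryo_muscle_microarray	l1_muscle_mrna
hsp-60	0	1	0
hsp-10	0	1	0
cct-1	0	0	0
cct-2	1	0	1
cct-3	0	0	0
cct-4	0	0	0
cct-5	1	1	1
cct-6	0	0	0
cct-7	0	1	0
cct-8	0	0	0
hsp-1	1	1	1
hsp-3	0	1	0
hsp-4	1	0	1
hsp-6	1	1	1
hsp-70	1	0	1
f44e5.4	0	1	0
f44e5.5	1	0	1
c12c8.1	1	1	1
f11f1.1	1	1	1
stc-1	1	0	1
t14g8.3	0	1	0
c30c11.4	0	1	0
hsp-110	1	0	1
dnj-1	0	1	0
dnj-2	0	0	0
dnj-3	1	0	1
dnj-4	1	1	1
dnj-5	0	1	0
dnj-6	1	0	1
dnj-7	1	1	1
dnj-8	0	1	0
dnj-9	0	0	0
dnj-10	0	0	0
dnj-11	0	0	0
dnj-12	1	0	1
dnj-13	1	1	1
dnj-14	0	0	0
dnj-15	0	0	0
dnj-16	0	0	0
dnj-17	0	0	0
dnj-18	0	0	0
dnj-19	0	0	0
dnj-20	0	0	0
dnj-21	0	0	0
dnj-22	0	0	0
dnj-23	0	0	0
dnj-24	0	1	0
dnj-25	0	0	0
dnj-26	0	0	0
dnj-27	0	0	0
dnj-28	0	0	0
dnj-29	0	0	0
dnj-30	0	0	0
rme-8	0	0	0
unc-23	1	1	1
t05c3.5	0	0	0
y73b6bl.12	0	0	0
f39b2.10	0	0	0
c08h9.14	1	0	1
daf-21	0	0	0
sti-1	1	1	1
c01g10.8	0	1	0
cdc-37	1	0	1
pph-5	1	1	1
fkb-6	0	0	0
unc-45	0	1	0
chn-1	1	1	1
r05f9.10	1	0	1
sgt-1	1	1	1
tah-1	1	0	1
ppt-1	0	1	0
aip-1	0	0	0
hsp-12.1	1	1	1
hsp-12.2	0	1	0
hsp-12.3	1	0	1
hsp-12.6	0	0	0
hsp-16.1	0	0	0
hsp-16.2	0	0	0
hsp-16.11	0	0	0
hsp-16.41	1	1	1
hsp-16.48	0	0	0
hsp-16.49	0	0	0
hsp-17	0	0	0
hsp-25	0	0	0
hsp-43	0	0	0
sip-1	0	1	0
f08h9.3	1	0	1
f08h9.4	0	0	0
pfd-1	0	0	0
pfd-2	0	0	0
pfd-3	0	0	0
pfd-4	0	0	0
pfd-5	0	0	0
pfd-6	0	0	0
nud-1	0	0	0
c17g10.2	0	0	0
b0035.14	0	0	0
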