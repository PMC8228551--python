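study_id	mirna_id	region	direction
s1	hsa-let-7b	substantia_nigra	up
s1	hsa-let-7d-5p	other	up
s1	hsa-let-7f-5p	other	up
s1	hsa-miR-106a	substantia_nigra	up
s1	hsa-miR-106b-5p	other	up
s1	hsa-miR-126	substantia_nigra	up
s1	hsa-miR-132	substantia_nigra	up
s1	hsa-miR-135a	substantia_nigra	up
s1	hsa-miR-135b	substantia_nigra	up
s1	hsa-miR-144	other	up
s1	hsa-miR-144-3p	other	up
s1	hsa-miR-144-5p	other	up
s1	hsa-miR-145	substantia_nigra	up
s1	hsa-miR-148a	substantia_nigra	up
s1	hsa-miR-151b	other	up
s1	hsa-miR-15b-5p	other	up
s1	hsa-miR-16-2-3p	other	up
s1	hsa-miR-181a-5p	other	up
s1	hsa-miR-184	substantia_nigra	up
s1	hsa-miR-198	substantia_nigra	up
s1	hsa-miR-199b	other	up
s1	hsa-miR-204-5p	putamen	up
s1	hsa-miR-208b	substantia_nigra	up
s1	hsa-miR-21 *	substantia_nigra	up
s1	hsa-miR-216b-5p	other	up
s1	hsa-miR-221	other	up
s1	hsa-miR-221-3p	putamen	up
s1	hsa-miR-223	substantia_nigra	up
s1	hsa-miR-224	substantia_nigra	up
s1	hsa-miR-26a	substantia_nigra	up
s1	hsa-miR-26b	substantia_nigra	up
s1	hsa-miR-27a	substantia_nigra	up
s1	hsa-miR-28-5p	substantia_nigra	up
s1	hsa-miR-299-5p	substantia_nigra	up
s1	hsa-miR-301b	substantia_nigra	up
s1	hsa-miR-3117-3p	other	up
s1	hsa-miR-3195	putamen	up
s1	hsa-miR-330-5p	substantia_nigra	up
s1	hsa-miR-335	substantia_nigra	up
s1	hsa-miR-337-5p	substantia_nigra	up
s1	hsa-miR-339-5p	substantia_nigra	up
s1	hsa-miR-373 *	substantia_nigra	up
s1	hsa-miR-374a	substantia_nigra	up
s1	hsa-miR-376c-5p	other	up
s1	hsa-miR-425-5p	putamen	up
s1	hsa-miR-4443	other	up
s1	hsa-miR-454-3p	other	up
s1	hsa-miR-485-3p	putamen	up
s1	hsa-miR-485-5p	substantia_nigra	up
s1	hsa-miR-488	other	up
s1	hsa-miR-5100	other	up
s1	hsa-miR-516b-5p	other	up
s1	hsa-miR-542-3p	substantia_nigra	up
s1	hsa-miR-544	other	up
s1	hsa-miR-5690	other	up
s1	hsa-miR-92a	substantia_nigra	up
s1	hsa-miR-92a-3p	other	up
s1	hsa-miR-92b-3p	other	up
s1	hsa-miR-93-5p	other	up
s1	hsa-miR-95	substantia_nigra	up
s1	hsa-miR-95	putamen	up
s1	hsa-miR-10b-5p	other	down
s1	hsa-miR-124	other	down
s1	hsa-miR-1294	other	down
s1	hsa-miR-129-5p	other	down
s1	hsa-miR-132-3p	other	down
s1	hsa-miR-132-5p	other	down
s1	hsa-miR-133b	substantia_nigra	down
s3	hsa-miR-144	other	down
s1	hsa-miR-145-5p	other	down
s1	hsa-miR-148b-3p	other	down
s1	hsa-miR-155-5p	putamen	down
s1	hsa-miR-205	other	down
s1	hsa-miR-212-5p	other	down
s1	hsa-miR-217	other	down
s1	hsa-miR-218	other	down
s1	hsa-miR-219-2-3p	putamen	down
s1	hsa-miR-3200-3p	putamen	down
s1	hsa-miR-320b	other	down
s1	hsa-miR-324-5p	other	down
s1	hsa-miR-338-5p	other	down
s1	hsa-miR-34b	substantia_nigra	down
s1	hsa-miR-34b	putamen	down
s1	hsa-miR-34c	substantia_nigra	down
s1	hsa-miR-362-5p	other	down
s1	hsa-miR-378c	other	down
s1	hsa-miR-380-5p	other	down
s1	hsa-miR-382-5p	putamen	down
s1	hsa-miR-421	putamen	down
s1	hsa-miR-423-5p	putamen	down
s1	hsa-miR-425	substantia_nigra	down
s1	hsa-miR-4421	putamen	down
s1	hsa-miR-490-5p	other	down
s1	hsa-miR-491-5p	other	down
s1	hsa-miR-532-5p	substantia_nigra	down
s1	hsa-miR-548d	substantia_nigra	down
s1	hsa-miR-6511a-5p	other	down
s1	hsa-miR-670-3p	other	down
s1	hsa-miR-671-5p	other	down
s1	hsa-miR-7	substantia_nigra	down
s1	hsa-miR-774	substantia_nigra	down
s2	hsa-miR-106a	substantia_nigra	up
s2	hsa-miR-34b	substantia_nigra	down
s2	hsa-miR-34b	putamen	down
s2	hsa-miR-95	substantia_nigra	up
s2	hsa-miR-95	putamen	up
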